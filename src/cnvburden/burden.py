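"""Genome-wide CNV burden analysis with permutation p-values.

For each sample the burden of CNVs is summarized by four features —
number of events, an indicator of carrying at least one event (whose
group mean is the proportion of samples with >= 1 event), total event
length in kb, and average event length in kb — computed for three event
classes (DelDup = deletions and duplications together, Del, Dup).

Case/control differences are tested by label permutation: the statistic
is mean(cases) - mean(controls) and the one-sided p-value is the
probability, under random relabeling, of a difference at least as large
as observed.  The full analysis grid crosses 2 CNV sets (all, rare) x
4 features x 3 event classes x 4 sample groups (ALL, AA, Hispanic, NHW)
= 96 tests, with a Bonferroni threshold of alpha / 96.

Covariates are deliberately not modeled: the burden test is a marginal
comparison of case and control burden distributions.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import DEL, DUP, CnvError, PhenotypeTable, ValidationError

__all__ = [
    "EVENT_CLASSES",
    "FEATURES",
    "BurdenFeatures",
    "BurdenTestResult",
    "compute_burden_features",
    "permutation_test",
    "PermutationResult",
    "run_burden_grid",
    "bonferroni_threshold",
    "round_sig",
    "results_to_frame",
]

EVENT_CLASSES = ("DelDup", "Del", "Dup")
FEATURES = ("event_count", "proportion_with_event", "total_length_kb",
            "average_length_kb")
GRID_GROUPS = ("ALL", "AA", "Hispanic", "NHW")
CNV_SETS = ("all", "rare")


def _class_mask(frame: pd.DataFrame, event_class: str) -> pd.Series:
    if event_class == "DelDup":
        return frame["svtype"].isin([DEL, DUP])
    if event_class == "Del":
        return frame["svtype"] == DEL
    if event_class == "Dup":
        return frame["svtype"] == DUP
    raise ValidationError(f"unknown event class {event_class!r}")


@dataclass
class BurdenFeatures:
    """Per-sample burden features for one event class.

    ``per_sample`` is indexed by sample_id with columns event_count,
    total_length_kb and average_length_kb (NaN for samples with zero
    events, which are excluded from average-length statistics).
    ``proportion_by_group`` maps group label (including "ALL") to the
    fraction of its samples carrying >= 1 event.
    """

    event_class: str
    per_sample: pd.DataFrame
    proportion_by_group: dict[str, float]


def compute_burden_features(cohort: pd.DataFrame, phenotypes: PhenotypeTable,
                            event_class: str = "DelDup") -> BurdenFeatures:
    """Per-sample burden features for one event class.

    Every phenotyped sample contributes a row; samples with no event of
    the class get count 0, total 0 kb and an undefined (NaN) average
    length. Group proportions are computed over all samples of the group.
    """
    sub = cohort[_class_mask(cohort, event_class)]
    lengths_kb = (sub["end"] - sub["start"]) / 1000.0
    counts = sub.groupby("sample_id").size()
    totals = lengths_kb.groupby(sub["sample_id"]).sum()
    samples = phenotypes.sample_ids
    per_sample = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    per_sample["event_count"] = counts.reindex(samples).fillna(0).astype(int)
    per_sample["total_length_kb"] = totals.reindex(samples).fillna(0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        per_sample["average_length_kb"] = np.where(
            per_sample["event_count"] > 0,
            per_sample["total_length_kb"] / per_sample["event_count"],
            np.nan,
        )
    has_event = per_sample["event_count"] > 0
    proportions = {"ALL": float(has_event.mean())}
    for group in phenotypes.frame["group"].unique():
        members = phenotypes.samples_in_group(group)
        proportions[group] = float(has_event.loc[members].mean())
    return BurdenFeatures(event_class, per_sample, proportions)


@dataclass(frozen=True)
class PermutationResult:
    p_value: float
    observed: float
    n_permutations: int
    exhaustive: bool
    mean_case: float
    mean_control: float


def _nan_group_means(values: np.ndarray, case_mask: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mc = np.nanmean(values[case_mask]) if case_mask.any() else np.nan
        mk = np.nanmean(values[~case_mask]) if (~case_mask).any() else np.nan
    return mc, mk


def permutation_test(values: Sequence[float], is_case: Sequence[bool],
                     n_permutations: int = 500_000, seed: int | None = 0,
                     alternative: str = "greater",
                     method: str = "auto") -> PermutationResult:
    """One-sided permutation test of mean(case) - mean(control).

    Case/control labels are permuted uniformly with a seeded generator.
    When the number of distinct label assignments C(n, n_case) does not
    exceed ``n_permutations`` they are enumerated exhaustively and
    p = #{assignments with statistic >= observed} / #assignments (the
    identity assignment guarantees p >= 1/#assignments); otherwise the
    Monte-Carlo estimate p = (1 + #{stat >= observed}) / (1 + N) is used,
    which never returns 0. NaN values (undefined per-sample statistics)
    are ignored within each relabeled group; if every relabeled value of a
    group is NaN that permutation counts as non-exceeding.

    With a constant statistic across samples every permutation ties the
    observed difference of 0 and p = 1.

    ``method`` is "auto" (exhaustive when feasible), "exhaustive" (error
    if C(n, n_case) > n_permutations) or "montecarlo" (always sample).
    """
    values = np.asarray(values, dtype=float)
    case = np.asarray(is_case, dtype=bool)
    n = len(values)
    if len(case) != n:
        raise ValidationError("values and labels differ in length")
    n_case = int(case.sum())
    if n_case == 0 or n_case == n:
        raise CnvError("need at least one case and one control")
    if alternative not in ("greater", "two-sided"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    mean_case, mean_control = _nan_group_means(values, case)
    observed = mean_case - mean_control
    if math.isnan(observed):
        # a group with no defined statistic cannot be tested
        return PermutationResult(math.nan, observed, 0, False,
                                 mean_case, mean_control)

    def stat_of(stats: np.ndarray) -> np.ndarray:
        return np.abs(stats) if alternative == "two-sided" else stats

    if method not in ("auto", "exhaustive", "montecarlo"):
        raise ValidationError(f"unknown method {method!r}")
    target = stat_of(np.array([observed]))[0]
    n_assignments = math.comb(n, n_case)
    if method == "exhaustive" and n_assignments > n_permutations:
        raise CnvError(
            f"{n_assignments} label assignments exceed the permutation budget")
    exhaustive = (method == "exhaustive"
                  or (method == "auto" and n_assignments <= n_permutations))
    if exhaustive:
        if not np.isnan(values).any():
            combos = np.fromiter(
                itertools.chain.from_iterable(
                    itertools.combinations(range(n), n_case)),
                dtype=np.intp, count=n_assignments * n_case,
            ).reshape(n_assignments, n_case)
            case_sum = values[combos].sum(axis=1)
            total = values.sum()
            stats = case_sum / n_case - (total - case_sum) / (n - n_case)
            exceed = int(np.sum(stat_of(stats) >= target - 1e-12))
        else:
            exceed = 0
            for combo in itertools.combinations(range(n), n_case):
                mask = np.zeros(n, dtype=bool)
                mask[list(combo)] = True
                mc, mk = _nan_group_means(values, mask)
                s = mc - mk
                if not math.isnan(s) and stat_of(np.array([s]))[0] >= target - 1e-12:
                    exceed += 1
        return PermutationResult(exceed / n_assignments, observed,
                                 n_assignments, True, mean_case, mean_control)

    rng = np.random.default_rng(seed)
    exceed = 0
    batch = 2000
    done = 0
    nan_free = not np.isnan(values).any()
    while done < n_permutations:
        b = min(batch, n_permutations - done)
        # each row: a uniformly random subset of size n_case as "cases"
        order = np.argsort(rng.random((b, n)), axis=1)
        case_idx = order[:, :n_case]
        if nan_free:
            case_sum = values[case_idx].sum(axis=1)
            total = values.sum()
            stats = case_sum / n_case - (total - case_sum) / (n - n_case)
        else:
            perm_vals = values[order]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mc = np.nanmean(perm_vals[:, :n_case], axis=1)
                mk = np.nanmean(perm_vals[:, n_case:], axis=1)
            stats = mc - mk
        s = stat_of(stats)
        exceed += int(np.sum(s >= target - 1e-12))
        done += b
    p = (1 + exceed) / (1 + n_permutations)
    return PermutationResult(p, observed, n_permutations, False,
                             mean_case, mean_control)


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 96) -> float:
    """Bonferroni-corrected significance threshold alpha / n_tests."""
    if alpha <= 0:
        raise ValidationError("alpha must be positive")
    if n_tests < 1:
        raise ValidationError("n_tests must be >= 1")
    return alpha / n_tests


def round_sig(x: float, digits: int = 3) -> float:
    """Round to a number of significant figures (for reporting)."""
    if x == 0 or math.isnan(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + digits - 1)


@dataclass(frozen=True)
class BurdenTestResult:
    """One cell of the burden analysis grid."""

    cnv_set: str
    feature: str
    event_class: str
    group: str
    mean_case: float
    mean_control: float
    p_value: float
    n_permutations: int
    seed: int
    significant: bool
    available: bool = True


def _feature_values(features: BurdenFeatures, feature: str) -> pd.Series:
    if feature == "event_count":
        return features.per_sample["event_count"].astype(float)
    if feature == "proportion_with_event":
        return (features.per_sample["event_count"] > 0).astype(float)
    if feature == "total_length_kb":
        return features.per_sample["total_length_kb"]
    if feature == "average_length_kb":
        return features.per_sample["average_length_kb"]
    raise ValidationError(f"unknown feature {feature!r}")


def run_burden_grid(all_cnvs: pd.DataFrame, rare: pd.DataFrame,
                    phenotypes: PhenotypeTable,
                    n_permutations: int = 500_000, seed: int = 0,
                    alpha: float = 0.05,
                    groups: Sequence[str] = GRID_GROUPS
                    ) -> list[BurdenTestResult]:
    """Run the full 2 x 4 x 3 x 4 burden grid (96 tests by default).

    Each cell permutes labels within its sample group and reports the
    case mean, control mean and one-sided p-value; ``significant`` marks
    cells below the Bonferroni threshold alpha / n_cells. Cells whose
    group has no samples, no cases or no controls are returned with
    ``available=False`` and p = NaN so the grid shape stays complete.
    Per-cell generator seeds are spawned deterministically from ``seed``.
    """
    tables = {"all": all_cnvs, "rare": rare}
    cells = list(itertools.product(CNV_SETS, FEATURES, EVENT_CLASSES, groups))
    threshold = bonferroni_threshold(alpha, len(cells))
    is_case_all = phenotypes.is_case()
    # cache features per (set, class)
    feat_cache = {
        (s, c): compute_burden_features(tables[s], phenotypes, c)
        for s in CNV_SETS for c in EVENT_CLASSES
    }
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(cells))]
    results = []
    for (cnv_set, feature, event_class, group), cell_seed in zip(cells, child_seeds):
        members = phenotypes.samples_in_group(group)
        values = _feature_values(feat_cache[(cnv_set, event_class)], feature)
        vals = values.loc[members].to_numpy()
        labels = is_case_all.loc[members].to_numpy()
        if len(members) == 0 or labels.all() or not labels.any():
            results.append(BurdenTestResult(
                cnv_set, feature, event_class, group, math.nan, math.nan,
                math.nan, 0, cell_seed, False, available=False))
            continue
        res = permutation_test(vals, labels, n_permutations, cell_seed)
        results.append(BurdenTestResult(
            cnv_set, feature, event_class, group,
            res.mean_case, res.mean_control, res.p_value,
            res.n_permutations, cell_seed,
            bool(not math.isnan(res.p_value) and res.p_value < threshold),
            available=not math.isnan(res.p_value)))
    return results


def results_to_frame(results: Sequence[BurdenTestResult]) -> pd.DataFrame:
    """Tabulate grid results (one row per cell)."""
    return pd.DataFrame([r.__dict__ for r in results])
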