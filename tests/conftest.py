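import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cnvburden import PhenotypeTable, SimulationConfig

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale simulation: 20 samples on a 150-kb two-chromosome genome."""
    return SimulationConfig(
        seed=11,
        n_samples=20,
        n_cases=10,
        n_pool_cnvs=30,
        chromosome_lengths={"chr1": 90_000, "chr2": 60_000},
    )


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, small_config):
    """A complete on-disk fixture set written once per session."""
    from cnvburden import write_fixtures

    out = tmp_path_factory.mktemp("fixtures")
    return write_fixtures(small_config, out)


@pytest.fixture()
def four_group_phenotypes() -> PhenotypeTable:
    """16 samples: 4 groups x (2 cases + 2 controls)."""
    rows = []
    i = 0
    for group in ("AA", "Hispanic", "NHW", "Other"):
        for status in ("case", "case", "control", "control"):
            i += 1
            rows.append((f"S{i:02d}", f"S{i:02d}", status, group))
    return PhenotypeTable(
        pd.DataFrame(rows, columns=["sample_id", "family_id", "status", "group"])
    )


@pytest.fixture()
def random_cohort(four_group_phenotypes) -> pd.DataFrame:
    """Random consolidated cohort table over the 16 phenotyped samples."""
    rng = np.random.default_rng(7)
    rows = []
    for sample in four_group_phenotypes.sample_ids:
        n = rng.integers(1, 6)
        starts = np.sort(rng.choice(np.arange(0, 50_000, 100), size=n, replace=False))
        for s in starts:
            length = int(rng.integers(200, 3_000))
            svtype = "DEL" if rng.random() < 0.6 else "DUP"
            cn = (1 if svtype == "DEL" else 3)
            rows.append(("chr1", int(s), int(s) + length, svtype, cn, sample, "sim"))
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "svtype",
                                        "copy_number", "sample_id", "source"])
    # samples' own calls may overlap as drawn; consolidate per sample
    from cnvburden import consolidate_sample_cnvs, SampleCallset
    from cnvburden.model import frame_to_calls, calls_to_frame

    out = []
    for sample, grp in frame.groupby("sample_id"):
        cs = SampleCallset(sample, tuple(frame_to_calls(grp)))
        out.extend(consolidate_sample_cnvs(cs).calls)
    res = calls_to_frame(out)
    return res.sort_values(["chrom", "start", "end", "sample_id"]).reset_index(drop=True)
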