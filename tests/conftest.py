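import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from translomap import ScenarioConfig, build_scenario, load_table1

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scen():
    """The default desk-scale scenario (seeded; identical across tests)."""
    return build_scenario()


@pytest.fixture(scope="session")
def table1():
    """(MarkerMap, RetentionMatrix) of the packaged hybrid-panel fixture."""
    return load_table1()


@pytest.fixture(scope="session")
def table1_target_markers(table1):
    """The 25 markers on the two translocated chromosomes, in row order."""
    markers, matrix = table1
    on_target = set(markers.df[markers.df["chrom"].isin(["SSC3", "SSC4"])]["name"])
    return [m for m in matrix.markers if m in on_target]


def small_config(rng: np.random.Generator, del_len: int | None = None) -> ScenarioConfig:
    """A random compact scenario config for fuzzing (fast to materialize)."""
    len_a = int(rng.integers(6_000, 15_000))
    len_b = int(rng.integers(8_000, 20_000))
    pos_a = int(rng.integers(1_000, len_a - 1_000))
    pos_b = int(rng.integers(1_000, len_b - 1_000))
    if del_len is None:
        del_len = int(rng.integers(0, 18))
    motif = "".join(rng.choice(list("ACGT"), del_len))
    return ScenarioConfig(
        name="fuzz",
        len_a=len_a,
        len_b=len_b,
        pos_a=pos_a,
        pos_b=pos_b,
        del_motif=motif,
        n_microsat_a=8,
        n_microsat_b=8,
        snp_spacing=300,
        snp_gap_radius=400,
    )
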