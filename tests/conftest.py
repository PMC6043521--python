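import numpy as np
import pytest

from phytkit.synthetic import (
    BackgroundSpec,
    PlantedSbtSpec,
    make_background_proteome,
    make_planted_sbt,
)


@pytest.fixture(scope="session")
def background_spec() -> BackgroundSpec:
    return BackgroundSpec(n_proteins=60, length_range=(200, 400), seed=42)


@pytest.fixture(scope="session")
def background_proteome(background_spec):
    return make_background_proteome(background_spec)


@pytest.fixture(scope="session")
def planted_candidate():
    """One complete Asp-P1, His331-type planted subtilase with truth."""
    spec = PlantedSbtSpec(
        id="phyt1", total_length=720, junction_index=120,
        p1_residue="D", residue331_analog="H", seed=7,
    )
    return make_planted_sbt(spec)


@pytest.fixture(scope="session")
def planted_noncandidate():
    """A complete subtilase with the predominant His at P1."""
    spec = PlantedSbtSpec(
        id="sbt_h", total_length=700, junction_index=110,
        p1_residue="H", residue331_analog="S", seed=8,
    )
    return make_planted_sbt(spec)


def make_family(n_candidates=3, n_others=5, n_decoys=10, seed=100):
    """Small planted family + decoys with full truth bookkeeping."""
    rng = np.random.default_rng(seed)
    records, truths = [], []
    for i in range(n_candidates + n_others):
        p1 = "D" if i < n_candidates else "H"
        spec = PlantedSbtSpec(
            id=f"sbt{i:03d}",
            total_length=int(rng.integers(650, 801)),
            junction_index=int(rng.integers(90, 160)),
            p1_residue=p1,
            residue331_analog="H" if p1 == "D" else "S",
            seed=int(rng.integers(0, 2**31)),
        )
        rec, truth = make_planted_sbt(spec)
        records.append(rec)
        truths.append(truth)
    decoys = make_background_proteome(BackgroundSpec(
        n_proteins=n_decoys, length_range=(300, 900),
        seed=int(rng.integers(0, 2**31)),
    ))
    return records, truths, decoys
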