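"""Composition glue: build and analyze a full planted subtilase family.

``make_tomato_like_family`` generates a synthetic family shaped like the
curated tomato subtilase set: 82 complete subtilases of which 12 carry Asp
at P1 — 5 His-type, 1 Lys-type and 6 Gly-type at the residue-331 position —
the remainder carrying the predominant His at P1, plus unrelated decoy
proteins.  ``screen_and_classify`` runs the complete screening, junction
calling and classification chain and returns the recovered counts.
"""

from __future__ import annotations

import numpy as np

from .junctions import call_junction, classify_phytaspase
from .screen import annotate_architecture, completeness_filter
from .synthetic import (
    BackgroundSpec,
    PlantedSbtSpec,
    SbtTruth,
    make_background_proteome,
    make_planted_sbt,
)
from .types import JunctionUncallableError, ProteinRecord, ReferenceJunction

#: Residue-331 composition of the 12 Asp-P1 candidates in the curated
#: tomato family: 5 His-type, 1 Lys-type, 6 Gly-type.
CANDIDATE_331 = "H" * 5 + "K" + "G" * 6


def make_tomato_like_family(
    seed: int = 0,
    n_family: int = 82,
    n_decoys: int = 120,
) -> tuple[list[ProteinRecord], list[SbtTruth], list[ProteinRecord], ReferenceJunction]:
    """Planted family + decoys + an annotated reference for junction calls.

    The first 12 family members are Asp-P1 candidates with the 5/1/6
    His/Lys/Gly residue-331 composition; the rest carry His at P1.  The
    reference is an extra planted subtilase (not part of the family), in
    the role of a characterized relative with a known junction.
    """
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    truths: list[SbtTruth] = []
    for i in range(n_family):
        if i < len(CANDIDATE_331):
            p1, res331 = "D", CANDIDATE_331[i]
        else:
            p1, res331 = "H", "S"
        spec = PlantedSbtSpec(
            id=f"fam{i:03d}",
            total_length=int(rng.integers(650, 801)),
            junction_index=int(rng.integers(90, 160)),
            p1_residue=p1,
            residue331_analog=res331,
            seed=int(rng.integers(0, 2**31)),
        )
        rec, truth = make_planted_sbt(spec)
        records.append(rec)
        truths.append(truth)
    decoys = make_background_proteome(BackgroundSpec(
        n_proteins=n_decoys, length_range=(250, 900),
        seed=int(rng.integers(0, 2**31)),
    ))
    ref_rec, ref_truth = make_planted_sbt(PlantedSbtSpec(
        id="reference", total_length=750, junction_index=140,
        p1_residue="H", residue331_analog="H",
        seed=int(rng.integers(0, 2**31)),
    ))
    reference = ReferenceJunction(
        id="reference", sequence=ref_rec.sequence,
        junction_index=ref_truth.junction_index,
        res331_index=ref_truth.residue331_index,
    )
    return records, truths, decoys, reference


def screen_and_classify(
    proteins: list[ProteinRecord], reference: ReferenceJunction
) -> dict[str, int]:
    """Full chain: annotate -> completeness filter -> junction -> classify.

    Returns counts of curated family members, Asp-P1 candidates, and the
    His/Lys/Gly-type subtype tallies among them.
    """
    architectures = {p.id: annotate_architecture(p) for p in proteins}
    screened = completeness_filter(proteins, architectures)
    retained = {p.id: p for p in proteins if p.id in screened.retained}
    counts = {"curated": len(retained), "asp_p1": 0,
              "his_type": 0, "lys_type": 0, "gly_type": 0, "uncallable": 0}
    for protein in retained.values():
        try:
            call, res331 = call_junction(protein, [reference])
        except JunctionUncallableError:
            counts["uncallable"] += 1
            continue
        verdict = classify_phytaspase(call, res331)
        if verdict.is_candidate:
            counts["asp_p1"] += 1
            key = {"His-type": "his_type", "Lys-type": "lys_type",
                   "Gly-type": "gly_type"}.get(verdict.subtype)
            if key:
                counts[key] += 1
    return counts
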