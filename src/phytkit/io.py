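"""Readers and writers for the standard formats the pipeline touches:
FASTA proteomes, GFF3 gene coordinates, window/fragment TSVs, trace CSVs,
specificity-model JSON, truth sidecars and PNG images."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import CleavageWindow, FluorescenceTrace, GeneCoordinate, ProteinRecord

PathLike = Union[str, Path]


def read_fasta(path: PathLike) -> list[ProteinRecord]:
    """Multi-record FASTA reader (wrapped lines and CRLF tolerated)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(
            id=rec.id,
            sequence=str(rec.seq).upper().replace("*", ""),
            description=rec.description if rec.description != rec.id else None,
        ))
    return records


def read_fasta_aligned(path: PathLike) -> list["AlignedRow"]:
    """Aligned-FASTA reader: rows keep their gap characters."""
    return [
        AlignedRow(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


class AlignedRow:
    """One row of a multiple sequence alignment (gaps allowed)."""

    __slots__ = ("id", "sequence")

    def __init__(self, id: str, sequence: str):
        self.id = id
        self.sequence = sequence


def write_fasta(records: Iterable[ProteinRecord], path: PathLike) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def read_gff3_genes(path: PathLike) -> list[GeneCoordinate]:
    """Extract gene features from GFF3, preserving 1-based inclusive
    coordinates (any 0-based half-open arithmetic is internal to callers)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    genes = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(GeneCoordinate(
            gene_id=gene_id, chromosome=feat.seqid,
            start=feat.start, end=feat.end, strand=feat.strand or "+",
        ))
    return genes


def write_windows_tsv(windows: Sequence[CleavageWindow], path: PathLike) -> None:
    pd.DataFrame({"window": [w.residues for w in windows]}).to_csv(
        path, sep="\t", index=False
    )


def read_windows_tsv(path: PathLike) -> list[CleavageWindow]:
    df = pd.read_csv(path, sep="\t")
    return [CleavageWindow(residues=w) for w in df["window"]]


def read_trace_csv(path: PathLike) -> FluorescenceTrace:
    """Trace CSV with columns ``time`` (minutes) and ``value`` (RFU), plus
    optional ``enzyme``/``substrate``/``ph`` metadata columns."""
    df = pd.read_csv(path)
    meta = {}
    for col in ("enzyme", "substrate", "ph"):
        if col in df.columns:
            meta[col] = df[col].iloc[0]
    return FluorescenceTrace(
        times=tuple(float(t) for t in df["time"]),
        values=tuple(float(v) for v in df["value"]),
        enzyme=meta.get("enzyme"), substrate=meta.get("substrate"),
        ph=float(meta["ph"]) if "ph" in meta else None,
    )


def write_trace_csv(trace: FluorescenceTrace, path: PathLike) -> None:
    pd.DataFrame({"time": trace.times, "value": trace.values}).to_csv(
        path, index=False
    )


def write_model_json(model, path: PathLike) -> None:
    payload = {
        "weights": np.asarray(model.weights).tolist(),
        "mode": model.mode,
        "tau": model.tau,
        "steepness": model.steepness,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_model_json(path: PathLike):
    from .pics import SpecificityModel

    payload = json.loads(Path(path).read_text())
    return SpecificityModel(
        weights=np.asarray(payload["weights"], dtype=float),
        mode=payload.get("mode", "threshold"),
        tau=float(payload.get("tau", 0.0)),
        steepness=float(payload.get("steepness", 1.0)),
    )


def write_truth_json(truth, path: PathLike) -> None:
    """JSON truth sidecar for a generated dataset (dataclass or mapping)."""
    import dataclasses

    def default(obj):
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        raise TypeError(f"cannot serialize {type(obj)}")

    Path(path).write_text(json.dumps(truth, default=default, indent=1))


def read_truth_json(path: PathLike):
    return json.loads(Path(path).read_text())


def write_png(image: np.ndarray, path: PathLike) -> None:
    from PIL import Image

    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="L").save(str(path))


def read_image(path: PathLike) -> np.ndarray:
    from PIL import Image

    return np.asarray(Image.open(str(path)))
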