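"""Readers, writers and run manifests shared by all modules.

File dialects:

* genotypes: CSV ``individual,locus,allele1,allele2`` (both allele fields
  empty for a missing entry);
* allele frequencies: CSV ``locus,allele,frequency``;
* sequences: plain FASTA;
* sightings: CSV ``transect_id,stratum,distance_m``;
* effort: CSV ``transect_id,length_m,stratum``.

Every writer can attach a :class:`RunManifest` sidecar (``<path>.manifest
.json``) recording the command, resolved configuration, seed, package
version and input digests, sufficient to reproduce the output bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

from .distance import SightingRecord, Transect
from .popgen import AlleleFrequencyTable, GenotypeMatrix, SequenceSet

__all__ = [
    "ParseError",
    "RunManifest",
    "read_genotypes",
    "write_genotypes",
    "read_allele_frequencies",
    "write_allele_frequencies",
    "read_fasta",
    "write_fasta",
    "read_sightings",
    "write_sightings",
    "read_effort",
    "write_results",
]

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input file; the message cites the offending line."""


# ---------------------------------------------------------------------------
# manifests


@dataclass
class RunManifest:
    """Reproducibility record written alongside every CLI output."""

    command: str
    configuration: dict
    seed: Optional[int] = None
    package_version: str = ""
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    input_digests: dict = field(default_factory=dict)

    @staticmethod
    def digest(path: str | Path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()

    def write(self, output_path: str | Path) -> Path:
        sidecar = Path(str(output_path) + ".manifest.json")
        sidecar.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return sidecar


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read the long-format genotype CSV into a :class:`GenotypeMatrix`."""
    path = Path(path)
    df = _read_csv(path, ["individual", "locus", "allele1", "allele2"])
    individuals: list[str] = []
    loci: list[str] = []
    genotypes: dict[str, dict] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        ind, locus = str(row.individual), str(row.locus)
        a1 = "" if pd.isna(row.allele1) else str(row.allele1)
        a2 = "" if pd.isna(row.allele2) else str(row.allele2)
        if (a1 == "") != (a2 == ""):
            raise ParseError(
                f"{path}:{row_no}: half-missing genotype for {ind!r} at {locus!r}"
            )
        if ind not in genotypes:
            genotypes[ind] = {}
            individuals.append(ind)
        if locus not in loci:
            loci.append(locus)
        genotypes[ind][locus] = None if a1 == "" else (a1, a2)
    if not individuals:
        raise ParseError(f"{path}: no genotype rows")
    return GenotypeMatrix(individuals=individuals, loci=loci, genotypes=genotypes)


def write_genotypes(g: GenotypeMatrix, path: str | Path) -> None:
    g.to_long_frame().to_csv(path, index=False)


def read_allele_frequencies(path: str | Path) -> AlleleFrequencyTable:
    df = _read_csv(Path(path), ["locus", "allele", "frequency"])
    try:
        return AlleleFrequencyTable.from_frame(df)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_allele_frequencies(t: AlleleFrequencyTable, path: str | Path) -> None:
    t.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# sequences


def read_fasta(path: str | Path) -> SequenceSet:
    """Read an aligned FASTA; raggedness is rejected by the container."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    return SequenceSet(records=records)


def write_fasta(seqs: SequenceSet, path: str | Path) -> None:
    SeqIO.write(seqs.records, str(path), "fasta")


# ---------------------------------------------------------------------------
# sightings / effort


def read_sightings(path: str | Path) -> list[SightingRecord]:
    path = Path(path)
    df = _read_csv(path, ["transect_id", "stratum", "distance_m"])
    records = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                SightingRecord(
                    transect_id=str(row.transect_id),
                    stratum=str(row.stratum),
                    perpendicular_distance=float(row.distance_m),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}:{row_no}: {exc}") from exc
    if not records:
        raise ParseError(f"{path}: no sighting rows")
    return records


def write_sightings(records: list[SightingRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "transect_id": [r.transect_id for r in records],
            "stratum": [r.stratum for r in records],
            "distance_m": [r.perpendicular_distance for r in records],
        }
    ).to_csv(path, index=False)


def read_effort(path: str | Path) -> list[Transect]:
    path = Path(path)
    df = _read_csv(path, ["transect_id", "length_m", "stratum"])
    out = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                Transect(
                    transect_id=str(row.transect_id),
                    stratum=str(row.stratum),
                    length_m=float(row.length_m),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}:{row_no}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# results


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results(
    obj,
    path: str | Path,
    fmt: str = "json",
    manifest: Optional[RunManifest] = None,
) -> None:
    """Write a results object (summary, table or density) to CSV/JSON.

    Objects exposing ``to_dict``/``to_frame`` are serialised through
    those; DataFrames go straight to the chosen format.  A manifest, when
    given, is written as a ``.manifest.json`` sidecar.
    """
    path = Path(path)
    if fmt not in ("csv", "json"):
        raise ValueError(f"unknown results format {fmt!r}")
    if isinstance(obj, pd.DataFrame):
        payload: object = obj
    elif hasattr(obj, "to_frame"):
        payload = obj.to_frame()
    elif hasattr(obj, "to_dict"):
        payload = obj.to_dict()
    elif dataclasses.is_dataclass(obj):
        payload = dataclasses.asdict(obj)
    else:
        payload = obj

    if fmt == "csv":
        if not isinstance(payload, pd.DataFrame):
            payload = pd.json_normalize(_jsonable(payload))
        payload.to_csv(path, index=False)
    else:
        if isinstance(payload, pd.DataFrame):
            payload = payload.to_dict(orient="records")
        path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")
    if manifest is not None:
        manifest.write(path)


def _read_csv(path: Path, required: list[str]) -> pd.DataFrame:
    if not Path(path).exists():
        raise ParseError(f"{path}: file not found")
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df
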