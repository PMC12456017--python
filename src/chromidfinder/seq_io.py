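"""Sequence input/output and per-replicon statistics.

Replicons are plain nucleotide sequences over the alphabet {A, C, G, T, N}.
On input, lowercase letters are uppercased and every IUPAC ambiguity code
other than N is mapped to N, so downstream k-mer code can assume a 4-letter
alphabet plus a single gap/ambiguity symbol.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TYPE_CHECKING

import pandas as pd
from Bio import SeqIO

from .errors import EmptyInputError, FastaIOError, UndefinedGCError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .classify import ClassificationResult

_VALID = set("ACGTN")
# every byte that is not A/C/G/T/N after uppercasing becomes N
_NORMALIZE = bytes(
    (c if chr(c) in _VALID else ord("N")) for c in bytes(range(256)).upper()
)


def normalize_sequence(raw: str) -> str:
    """Uppercase and collapse non-ACGTN letters to N."""
    return raw.encode("ascii").translate(_NORMALIZE).decode("ascii")


@dataclass
class Replicon:
    """One nucleotide sequence: a putative chromosome, chromid, or plasmid.

    Parameters
    ----------
    id : str
        Record identifier, unique within a run.
    sequence : str
        DNA sequence; normalized to {A,C,G,T,N} on construction.
    source : str, optional
        Genome or sample of origin.
    """

    id: str
    sequence: str
    source: str | None = None

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)

    @property
    def length(self) -> int:
        """Replicon length in bp."""
        return len(self.sequence)


@dataclass
class GenomeAssembly:
    """An ordered collection of replicons belonging to one genome."""

    id: str
    replicons: list[Replicon] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rep in self.replicons:
            if rep.id in seen:
                raise ValidationError(f"duplicate replicon id {rep.id!r} in assembly {self.id!r}")
            seen.add(rep.id)

    def __len__(self) -> int:
        return len(self.replicons)


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(
    path: str | Path,
    mode: str = "per_genome",
    min_length: int = 0,
) -> list[GenomeAssembly]:
    """Read a (optionally gzipped) multi-FASTA file into assemblies.

    In ``per_genome`` mode the whole file is one :class:`GenomeAssembly` with
    one replicon per record. In ``pooled`` mode every record becomes an
    independent single-replicon assembly — the treatment used when replicon
    grouping is deliberately discarded, as with pooled MAG contigs.

    Parameters
    ----------
    path : path to FASTA or FASTA.gz file
    mode : ``"per_genome"`` or ``"pooled"``
    min_length : drop records shorter than this many bp (0 keeps everything)
    """
    if mode not in ("per_genome", "pooled"):
        raise ValidationError(f"unknown mode {mode!r}")
    path = Path(path)
    if not path.exists():
        raise FastaIOError(f"no such file: {path}")
    try:
        with _open_maybe_gzip(path) as handle:
            records = list(SeqIO.parse(handle, "fasta"))
    except (OSError, UnicodeDecodeError) as exc:
        raise FastaIOError(f"could not read {path}: {exc}") from exc
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    seen: set[str] = set()
    replicons = []
    for rec in records:
        if rec.id in seen:
            raise ValidationError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        rep = Replicon(id=rec.id, sequence=str(rec.seq), source=path.stem)
        if rep.length >= min_length:
            replicons.append(rep)
    if mode == "per_genome":
        return [GenomeAssembly(id=path.stem, replicons=replicons)]
    return [GenomeAssembly(id=rep.id, replicons=[rep]) for rep in replicons]


def write_fasta(replicons: Iterable[Replicon], path: str | Path) -> None:
    """Write replicons to a FASTA file (60-column wrapping)."""
    path = Path(path)
    try:
        with open(path, "w") as out:
            for rep in replicons:
                out.write(f">{rep.id}\n")
                for i in range(0, rep.length, 60):
                    out.write(rep.sequence[i : i + 60] + "\n")
    except OSError as exc:
        raise FastaIOError(f"could not write {path}: {exc}") from exc


def gc_content(replicon: Replicon | str) -> float:
    """GC fraction over non-N bases: (#G + #C) / (#A + #C + #G + #T).

    N bases are excluded from both numerator and denominator, so gapped MAG
    sequences are not biased toward the composition of their gap filler.

    Raises
    ------
    UndefinedGCError
        If the sequence is empty or all N.
    """
    seq = replicon.sequence if isinstance(replicon, Replicon) else normalize_sequence(replicon)
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise UndefinedGCError("GC content undefined: sequence has no non-N base")
    return gc / acgt


RESULT_COLUMNS = [
    "replicon_id",
    "source",
    "length",
    "gc_pct",
    "role",
    "center_id",
    "delta_gc",
    "tetra_dist",
    "n_rep",
    "n_par",
    "n_core",
    "n_dnaa",
]


def write_results(result: "ClassificationResult", path: str | Path, format: str = "tsv") -> None:
    """Write a classification result as TSV or JSON (one row/object per replicon)."""
    if format not in ("tsv", "json"):
        raise ValidationError(f"unknown output format {format!r}")
    path = Path(path)
    frame = result.to_frame()
    try:
        if format == "tsv":
            frame.to_csv(path, sep="\t", index=False)
        else:
            payload = {
                "mode": result.mode,
                "rows": json.loads(frame.to_json(orient="records")),
            }
            with open(path, "w") as out:
                json.dump(payload, out, indent=1, sort_keys=True)
                out.write("\n")
    except OSError as exc:
        raise FastaIOError(f"could not write {path}: {exc}") from exc


def read_results(path: str | Path, format: str = "tsv"):
    """Read back a result table written by :func:`write_results`.

    Returns a DataFrame for TSV, or the parsed JSON payload for JSON.
    """
    path = Path(path)
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    with open(path) as handle:
        return json.load(handle)
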