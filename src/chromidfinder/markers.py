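"""Gene prediction and marker detection for the four screening categories.

Replicon classification relies on four marker categories:

* ``REP``  — plasmid replication initiation proteins,
* ``PAR``  — plasmid partitioning proteins (ParA/ParB families),
* ``CORE`` — bacterial core genes carried by chromosomes across taxa,
* ``DNAA`` — the chromosomal replication initiator DnaA and its homologs.

A marker's category comes exclusively from the database manifest; it is
never guessed from the marker's name. Two scanner backends implement the
same contract: a profile-HMM search over user-supplied HMMER3 models
(via pyhmmer) and an exact amino-acid motif scanner used for self-contained
testing. Gene prediction likewise has two backends: the external
``prodigal`` gene caller and a built-in naive ORF finder.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from .errors import BackendUnavailableError, DatabaseError, ValidationError
from .seq_io import Replicon

CATEGORIES = ("REP", "PAR", "CORE", "DNAA")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _build_codon_lookup() -> np.ndarray:
    """aa byte per codon index c0*16 + c1*4 + c2 (A,C,G,T order); 64 = ambiguous -> X."""
    table = CodonTable.unambiguous_dna_by_id[11]
    bases = "ACGT"
    lut = np.full(65, ord("X"), dtype=np.uint8)
    for i, b0 in enumerate(bases):
        for j, b1 in enumerate(bases):
            for l, b2 in enumerate(bases):
                codon = b0 + b1 + b2
                idx = i * 16 + j * 4 + l
                if codon in table.stop_codons:
                    lut[idx] = ord("*")
                else:
                    lut[idx] = ord(table.forward_table[codon])
    return lut


_CODON_LUT = _build_codon_lookup()

_BASE_CODE = np.full(256, 64, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


def translate_frame(seq: str, offset: int) -> str:
    """Translate one reading frame (bacterial code); ambiguous codons give X."""
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)][offset:]
    n_codons = codes.size // 3
    if n_codons == 0:
        return ""
    c = codes[: n_codons * 3].reshape(n_codons, 3)
    idx = c[:, 0] * 16 + c[:, 1] * 4 + c[:, 2]
    idx[(c >= 4).any(axis=1)] = 64
    return _CODON_LUT[idx].tobytes().decode("ascii")


@dataclass
class Gene:
    """A predicted protein-coding gene with 1-based inclusive nucleotide coordinates."""

    protein: str
    start: int
    end: int
    strand: str  # "+" or "-"


@dataclass
class MarkerHit:
    replicon_id: str
    marker_id: str
    category: str
    score: float
    e_value: float

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown marker category {self.category!r}")


@dataclass
class MarkerProfile:
    """Distinct-marker counts per category for one replicon."""

    replicon_id: str
    n_rep: int = 0
    n_par: int = 0
    n_core: int = 0
    n_dnaa: int = 0

    @property
    def has_dnaa(self) -> bool:
        return self.n_dnaa > 0

    @property
    def total(self) -> int:
        return self.n_rep + self.n_par + self.n_core + self.n_dnaa


@dataclass
class MarkerModel:
    marker_id: str
    category: str
    model: object  # motif string or pyhmmer.plan7.HMM


@dataclass
class MarkerDatabase:
    """Marker models plus the manifest mapping each marker to its category."""

    backend: str  # "motif" | "hmm"
    entries: list[MarkerModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.backend not in ("motif", "hmm"):
            raise DatabaseError(f"unknown scanner backend {self.backend!r}")
        seen = set()
        for entry in self.entries:
            if entry.category not in CATEGORIES:
                raise DatabaseError(
                    f"marker {entry.marker_id!r} has unknown category {entry.category!r}"
                )
            if entry.marker_id in seen:
                raise DatabaseError(f"duplicate marker id {entry.marker_id!r}")
            seen.add(entry.marker_id)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def manifest(self) -> dict[str, str]:
        return {e.marker_id: e.category for e in self.entries}

    @classmethod
    def from_motifs(cls, motifs: dict[str, tuple[str, str]]) -> "MarkerDatabase":
        """Build a motif database from {marker_id: (category, amino-acid motif)}."""
        entries = [
            MarkerModel(marker_id=mid, category=cat, model=motif)
            for mid, (cat, motif) in motifs.items()
        ]
        return cls(backend="motif", entries=entries)

    @classmethod
    def from_motif_files(cls, motif_path: str | Path, manifest_path: str | Path) -> "MarkerDatabase":
        """Load a plain-text motif database (TSV: marker_id, motif) plus manifest."""
        manifest = _read_manifest(manifest_path)
        entries = []
        for line in _read_lines(motif_path):
            marker_id, motif = line.split("\t")[:2]
            if marker_id not in manifest:
                raise DatabaseError(f"marker {marker_id!r} missing from manifest")
            entries.append(MarkerModel(marker_id, manifest[marker_id], motif))
        return cls(backend="motif", entries=entries)

    @classmethod
    def from_hmm_files(cls, hmm_path: str | Path, manifest_path: str | Path) -> "MarkerDatabase":
        """Load HMMER3 models (a file or a directory of .hmm files) plus manifest."""
        import pyhmmer

        manifest = _read_manifest(manifest_path)
        hmm_path = Path(hmm_path)
        files = sorted(hmm_path.glob("*.hmm")) if hmm_path.is_dir() else [hmm_path]
        entries = []
        for file in files:
            try:
                with pyhmmer.plan7.HMMFile(str(file)) as handle:
                    for hmm in handle:
                        name = hmm.name
                        marker_id = name.decode() if isinstance(name, bytes) else name
                        if marker_id not in manifest:
                            raise DatabaseError(
                                f"marker {marker_id!r} from {file} missing from manifest"
                            )
                        entries.append(MarkerModel(marker_id, manifest[marker_id], hmm))
            except (OSError, ValueError) as exc:
                raise DatabaseError(f"could not read HMM file {file}: {exc}") from exc
        return cls(backend="hmm", entries=entries)


def _read_lines(path: str | Path) -> list[str]:
    try:
        with open(path) as handle:
            return [ln.rstrip("\n") for ln in handle if ln.strip() and not ln.startswith("#")]
    except OSError as exc:
        raise DatabaseError(f"could not read {path}: {exc}") from exc


def _read_manifest(path: str | Path) -> dict[str, str]:
    manifest = {}
    for line in _read_lines(path):
        marker_id, category = line.split("\t")[:2]
        manifest[marker_id] = category
    return manifest


def find_orfs_naive(sequence: str, min_aa: int = 30) -> list[Gene]:
    """Naive ORF finder: longest ORF per stop-to-stop segment, both strands.

    An ORF runs from the first ATG after the previous in-frame stop to the
    next in-frame stop and must encode at least ``min_aa`` residues. The
    reported protein excludes the stop; coordinates include the stop codon.
    """
    n = len(sequence)
    genes: list[Gene] = []
    for strand, seq in (("+", sequence), ("-", reverse_complement(sequence))):
        for offset in range(3):
            prot = translate_frame(seq, offset)
            seg_start = 0  # aa index where current stop-free segment begins
            pos = 0
            while True:
                stop = prot.find("*", pos)
                if stop == -1:
                    break  # trailing segment without stop: no complete ORF
                m = prot.find("M", seg_start, stop)
                if m != -1 and stop - m >= min_aa:
                    nt_a = offset + 3 * m + 1  # 1-based on current strand
                    nt_b = offset + 3 * (stop + 1)  # includes stop codon
                    if strand == "+":
                        start, end = nt_a, nt_b
                    else:
                        start, end = n - nt_b + 1, n - nt_a + 1
                    genes.append(Gene(protein=prot[m:stop], start=start, end=end, strand=strand))
                seg_start = stop + 1
                pos = stop + 1
    genes.sort(key=lambda g: (g.start, g.end, g.strand))
    return genes


def _predict_genes_prodigal(replicon: Replicon) -> list[Gene]:
    exe = shutil.which("prodigal")
    if exe is None:
        raise BackendUnavailableError(
            "prodigal not found on PATH; select the 'naive' gene backend instead"
        )
    with tempfile.TemporaryDirectory() as tmp:
        fna = Path(tmp) / "in.fna"
        faa = Path(tmp) / "out.faa"
        with open(fna, "w") as out:
            out.write(f">{replicon.id}\n{replicon.sequence}\n")
        subprocess.run(
            [exe, "-i", str(fna), "-a", str(faa), "-p", "meta", "-q", "-o", "/dev/null"],
            check=True,
            capture_output=True,
        )
        genes = []
        header, chunks = None, []
        lines = faa.read_text().splitlines() + [">"]
        for line in lines:
            if line.startswith(">"):
                if header is not None:
                    parts = [p.strip() for p in header.split("#")]
                    start, end, strand = int(parts[1]), int(parts[2]), parts[3]
                    genes.append(
                        Gene(
                            protein="".join(chunks).rstrip("*"),
                            start=start,
                            end=end,
                            strand="+" if strand == "1" else "-",
                        )
                    )
                header, chunks = line[1:], []
            else:
                chunks.append(line.strip())
    return genes


def predict_genes(
    replicon: Replicon,
    backend: str = "prodigal",
    min_aa: int = 30,
    min_length: int = 90,
) -> list[Gene]:
    """Predict protein-coding genes on a replicon.

    ``backend="prodigal"`` runs the external prokaryotic gene caller (meta
    mode); ``backend="naive"`` uses the built-in ORF finder, which needs no
    external tooling and is the default for the synthetic pipeline tests.
    Replicons shorter than ``min_length`` bp yield no genes.
    """
    if replicon.length < min_length:
        return []
    if backend == "naive":
        return find_orfs_naive(replicon.sequence, min_aa=min_aa)
    if backend == "prodigal":
        return _predict_genes_prodigal(replicon)
    raise BackendUnavailableError(f"unknown gene backend {backend!r}")


def _scan_motifs(proteins, db, replicon_id):
    hits = []
    for entry in db.entries:
        motif = entry.model
        for gene in proteins:
            if motif in gene.protein:
                hits.append(
                    MarkerHit(
                        replicon_id=replicon_id,
                        marker_id=entry.marker_id,
                        category=entry.category,
                        score=float(len(motif)),
                        e_value=0.0,
                    )
                )
    return hits


def _scan_hmms(proteins, db, replicon_id, e_threshold):
    import pyhmmer

    alphabet = pyhmmer.easel.Alphabet.amino()
    block = pyhmmer.easel.TextSequenceBlock(
        pyhmmer.easel.TextSequence(name=str(i).encode(), sequence=g.protein)
        for i, g in enumerate(proteins)
    ).digitize(alphabet)
    hits = []
    for entry in db.entries:
        hmm = entry.model
        # per-model gathering cutoffs override the global E-value threshold
        if hmm.cutoffs.gathering_available():
            pipeline = pyhmmer.plan7.Pipeline(alphabet, bit_cutoffs="gathering")
        else:
            pipeline = pyhmmer.plan7.Pipeline(alphabet, E=e_threshold)
        for hit in pipeline.search_hmm(hmm, block):
            if hit.included:
                hits.append(
                    MarkerHit(
                        replicon_id=replicon_id,
                        marker_id=entry.marker_id,
                        category=entry.category,
                        score=float(hit.score),
                        e_value=float(hit.evalue),
                    )
                )
    return hits


def scan_markers(
    proteins: list[Gene],
    db: MarkerDatabase,
    e_threshold: float = 1e-5,
    replicon_id: str = "",
) -> list[MarkerHit]:
    """Scan predicted proteins against the marker database.

    The motif backend reports a hit per (protein, marker) substring match
    with e_value 0; the HMM backend reports hmmsearch hits passing the
    full-sequence E-value threshold (or the model's gathering cutoff when
    it carries one).
    """
    if len(db) == 0:
        raise DatabaseError("marker database is empty")
    if not proteins:
        return []
    if db.backend == "motif":
        return _scan_motifs(proteins, db, replicon_id)
    return _scan_hmms(proteins, db, replicon_id, e_threshold)


def profile_replicon(replicon_id: str, hits: list[MarkerHit]) -> MarkerProfile:
    """Collapse hits into per-category distinct-marker counts.

    Multiple hits to one marker count once: the screening rules are
    presence/absence rules over distinct markers.
    """
    foreign = sorted({h.replicon_id for h in hits if h.replicon_id != replicon_id})
    if foreign:
        raise ValidationError(
            f"hits for {foreign} passed to profile of {replicon_id!r}"
        )
    distinct: dict[str, set[str]] = {cat: set() for cat in CATEGORIES}
    for hit in hits:
        distinct[hit.category].add(hit.marker_id)
    return MarkerProfile(
        replicon_id=replicon_id,
        n_rep=len(distinct["REP"]),
        n_par=len(distinct["PAR"]),
        n_core=len(distinct["CORE"]),
        n_dnaa=len(distinct["DNAA"]),
    )
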