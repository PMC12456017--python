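"""Seeded synthetic multipartite genomes with ground-truth labels.

Each synthetic assembly emulates the three replicon classes the classifier
must separate:

* a **chromosome** drawn from a Markov background model fitted to the
  target GC, carrying a planted DnaA marker gene (plus core genes);
* **chromids** drawn from the *same fitted model family* (so their
  tetranucleotide signature stays close to the chromosome's) with the GC
  target nudged by a small offset, carrying Rep, Par and core marker genes;
* **plasmids** drawn from a model offset in GC by several percentage
  points, carrying Rep and Par but no core gene (marker planting is
  selectable, so marker-withheld failure modes can be simulated too).

Planted genes are valid ORFs (ATG start, ≥30 sense codons, TAA stop) so
both gene-caller backends recover them, and each encodes one literal
amino-acid motif from the toy marker database below. All randomness flows
from a single integer seed; per-assembly seeds are derived as seed + index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from numba import njit

from .errors import ParameterError
from .markers import MarkerDatabase, reverse_complement
from .seq_io import GenomeAssembly, Replicon, write_fasta

#: Toy marker database used by the motif scanner backend in tests and
#: simulations: marker_id -> (category, amino-acid motif).
TOY_MARKERS: dict[str, tuple[str, str]] = {
    "dnaA": ("DNAA", "DNAAWHKRTELVQD"),
    "repA": ("REP", "WKRPLASREPKDEI"),
    "parA": ("PAR", "HQPARTWKDNLEMS"),
    "rpoB": ("CORE", "MCREGENAVKWTYD"),
    "gyrB": ("CORE", "GYRASECWKDLHTQ"),
}

from Bio.Data.CodonTable import unambiguous_dna_by_id as _codon_tables

_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(_codon_tables[11].forward_table.items()):
    _CODONS.setdefault(_aa, []).append(_codon)

_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_BASES = "ACGT"


def toy_marker_database() -> MarkerDatabase:
    """The motif-backend marker database matching the planted genes."""
    return MarkerDatabase.from_motifs(TOY_MARKERS)


@dataclass
class GeneratorParams:
    """Study conditions for the synthetic benchmark.

    Defaults describe a small multipartite genome: a 500 kb chromosome at
    60% GC, one 150 kb chromid whose GC is nudged by 0.3 percentage points,
    and one 40 kb plasmid offset by 5 percentage points — comfortably
    inside/outside the ±1 pp screening band respectively. ``plasmid_markers``
    selects the plasmid failure mode: ``"rep_par"`` (composition divergent,
    core gene absent), ``"none"`` (markers withheld) or ``"full"``.
    """

    chromosome_length: int = 500_000
    chromid_count: int = 1
    chromid_length: int = 150_000
    plasmid_count: int = 1
    plasmid_length: int = 40_000
    chromosome_gc: float = 0.60
    chromid_gc_offset: float = 0.3  # percentage points
    plasmid_gc_offset: float = 5.0  # percentage points
    markov_order: int = 1
    seed: int = 0
    plasmid_markers: str = "rep_par"

    def __post_init__(self) -> None:
        for name in ("chromosome_length", "chromid_length", "plasmid_length"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.chromid_count < 0 or self.plasmid_count < 0:
            raise ParameterError("replicon counts must be >= 0")
        if self.chromid_gc_offset < 0 or self.plasmid_gc_offset < 0:
            raise ParameterError("GC offsets must be >= 0")
        if not 0 < self.chromosome_gc < 1:
            raise ParameterError("chromosome_gc must be in (0, 1)")
        for off in (self.chromid_gc_offset, self.plasmid_gc_offset):
            if not 0 < self.chromosome_gc + off / 100 < 1:
                raise ParameterError("GC offset pushes target GC outside (0, 1)")
        if self.markov_order not in (0, 1):
            raise ParameterError("markov_order must be 0 or 1")
        if self.plasmid_markers not in ("rep_par", "none", "full"):
            raise ParameterError(f"unknown plasmid_markers mode {self.plasmid_markers!r}")


@dataclass
class SyntheticTruth:
    """Ground-truth labels and planted markers for generated replicons."""

    roles: dict[str, str] = field(default_factory=dict)  # id -> CHROMOSOME|CHROMID|PLASMID
    planted: dict[str, list[str]] = field(default_factory=dict)  # id -> marker ids
    params: GeneratorParams | None = None

    def merge(self, other: "SyntheticTruth") -> None:
        self.roles.update(other.roles)
        self.planted.update(other.planted)


# fixed dinucleotide bias giving the background model a non-trivial genomic
# signature; chosen strand-symmetric (B[a][b] == B[comp b][comp a])
_BIAS = np.ones((4, 4))
_BIAS[1, 2] = 0.25  # CG strongly depleted
_BIAS[2, 1] = 0.8   # GC
_BIAS[0, 0] = 1.6   # AA / TT enriched
_BIAS[3, 3] = 1.6
_BIAS[3, 0] = 0.6   # TA depleted
_BIAS[2, 2] = 1.25  # GG / CC enriched
_BIAS[1, 1] = 1.25


def _transition_matrix(base_probs: np.ndarray) -> np.ndarray:
    t = base_probs[None, :] * _BIAS
    return t / t.sum(axis=1, keepdims=True)


def _stationary(t: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(t.T)
    i = int(np.argmin(np.abs(vals - 1)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _fit_model(gc: float, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Fit (stationary, transition) so the chain's stationary GC equals ``gc``."""
    if order == 0:
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        return p, np.tile(p, (4, 1))
    lo, hi = 1e-6, 1 - 1e-6
    for _ in range(60):  # bisect the base-composition GC knob
        mid = (lo + hi) / 2
        p = np.array([(1 - mid) / 2, mid / 2, mid / 2, (1 - mid) / 2])
        t = _transition_matrix(p)
        if _stationary(t)[[1, 2]].sum() < gc:
            lo = mid
        else:
            hi = mid
    p = np.array([(1 - mid) / 2, mid / 2, mid / 2, (1 - mid) / 2])
    t = _transition_matrix(p)
    return _stationary(t), t


@njit
def _sample_chain(cum: np.ndarray, u: np.ndarray, first: int) -> np.ndarray:  # pragma: no cover
    n = u.shape[0]
    out = np.empty(n + 1, dtype=np.int8)
    out[0] = first
    state = first
    for i in range(n):
        r = u[i]
        row = cum[state]
        b = 0
        while r > row[b] and b < 3:
            b += 1
        out[i + 1] = b
        state = b
    return out


def _sample_background(length: int, gc: float, order: int, rng: np.random.Generator) -> str:
    pi, t = _fit_model(gc, order)
    if order == 0:
        codes = rng.choice(4, size=length, p=pi)
    else:
        first = int(rng.choice(4, p=pi))
        u = rng.random(length - 1)
        codes = _sample_chain(np.cumsum(t, axis=1), u, first)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[np.asarray(codes, dtype=np.int64)].tobytes().decode("ascii")


def _encode_protein(protein: str, rng: np.random.Generator) -> str:
    return "".join(_CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein)


def _plant_genes(
    background: str, marker_ids: list[str], rng: np.random.Generator
) -> tuple[str, list[str]]:
    """Embed one valid ORF per marker at non-overlapping random positions."""
    seq = list(background)
    occupied: list[tuple[int, int]] = []
    planted = []
    for marker_id in marker_ids:
        category, motif = TOY_MARKERS[marker_id]
        pad_front = "".join(rng.choice(list(_AA_ALPHABET), size=int(rng.integers(8, 14))))
        pad_back = "".join(rng.choice(list(_AA_ALPHABET), size=int(rng.integers(10, 16))))
        protein = "M" + pad_front + motif + pad_back
        gene = "ATG" + _encode_protein(protein[1:], rng) + "TAA"
        for _ in range(200):
            pos = int(rng.integers(0, len(seq) - len(gene)))
            if all(pos + len(gene) <= a or pos >= b for a, b in occupied):
                break
        else:  # pragma: no cover - only with absurdly dense planting
            raise ParameterError("could not place planted gene without overlap")
        if rng.random() < 0.5:
            gene = reverse_complement(gene)
        seq[pos : pos + len(gene)] = gene
        occupied.append((pos, pos + len(gene)))
        planted.append(marker_id)
    return "".join(seq), planted


def generate_assembly(params: GeneratorParams) -> tuple[GenomeAssembly, SyntheticTruth]:
    """Generate one multipartite assembly plus its ground truth (deterministic per seed)."""
    rng = np.random.default_rng(params.seed)
    gid = f"g{params.seed:05d}"
    truth = SyntheticTruth(params=params)
    replicons = []

    seq, planted = _plant_genes(
        _sample_background(params.chromosome_length, params.chromosome_gc, params.markov_order, rng),
        ["dnaA", "rpoB", "gyrB"],
        rng,
    )
    rid = f"{gid}_chromosome"
    replicons.append(Replicon(id=rid, sequence=seq, source=gid))
    truth.roles[rid] = "CHROMOSOME"
    truth.planted[rid] = planted

    chromid_gc = params.chromosome_gc + params.chromid_gc_offset / 100
    for j in range(params.chromid_count):
        seq, planted = _plant_genes(
            _sample_background(params.chromid_length, chromid_gc, params.markov_order, rng),
            ["repA", "parA", "rpoB"],
            rng,
        )
        rid = f"{gid}_chromid{j + 1}"
        replicons.append(Replicon(id=rid, sequence=seq, source=gid))
        truth.roles[rid] = "CHROMID"
        truth.planted[rid] = planted

    plasmid_gc = params.chromosome_gc + params.plasmid_gc_offset / 100
    plasmid_markers = {
        "rep_par": ["repA", "parA"],
        "none": [],
        "full": ["repA", "parA", "rpoB"],
    }[params.plasmid_markers]
    for j in range(params.plasmid_count):
        background = _sample_background(
            params.plasmid_length, plasmid_gc, params.markov_order, rng
        )
        seq, planted = _plant_genes(background, plasmid_markers, rng)
        rid = f"{gid}_plasmid{j + 1}"
        replicons.append(Replicon(id=rid, sequence=seq, source=gid))
        truth.roles[rid] = "PLASMID"
        truth.planted[rid] = planted

    return GenomeAssembly(id=gid, replicons=replicons), truth


def generate_benchmark(
    n_assemblies: int,
    params: GeneratorParams | None = None,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[Replicon], SyntheticTruth]:
    """Generate ``n_assemblies`` assemblies and pool their replicons.

    Genome groupings are stripped (every replicon becomes an independent
    pooled sequence). Per-assembly seeds are ``seed + index``. When
    ``out_dir`` is given, writes ``pool.fasta``, ``truth.tsv``,
    ``motifs.tsv`` and ``manifest.tsv`` for CLI use.
    """
    if n_assemblies < 1:
        raise ParameterError("n_assemblies must be >= 1")
    params = params or GeneratorParams()
    base_seed = params.seed if seed is None else seed
    pool: list[Replicon] = []
    truth = SyntheticTruth(params=params)
    for i in range(n_assemblies):
        assembly, t = generate_assembly(replace(params, seed=base_seed + i))
        pool.extend(assembly.replicons)
        truth.merge(t)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(pool, out_dir / "pool.fasta")
        write_truth(truth, out_dir / "truth.tsv")
        write_toy_database(out_dir)
    return pool, truth


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("replicon_id\ttrue_role\tplanted_markers\n")
        for rid, role in truth.roles.items():
            out.write(f"{rid}\t{role}\t{','.join(truth.planted.get(rid, []))}\n")


def read_truth(path: str | Path) -> dict[str, str]:
    roles = {}
    with open(path) as handle:
        next(handle)
        for line in handle:
            rid, role = line.rstrip("\n").split("\t")[:2]
            roles[rid] = role
    return roles


def write_toy_database(out_dir: str | Path) -> tuple[Path, Path]:
    """Write the toy motif database and its category manifest as TSV."""
    out_dir = Path(out_dir)
    motifs = out_dir / "motifs.tsv"
    manifest = out_dir / "manifest.tsv"
    with open(motifs, "w") as out:
        for mid, (_, motif) in TOY_MARKERS.items():
            out.write(f"{mid}\t{motif}\n")
    with open(manifest, "w") as out:
        for mid, (cat, _) in TOY_MARKERS.items():
            out.write(f"{mid}\t{cat}\n")
    return motifs, manifest
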