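"""Deterministic synthetic references with the repeat architecture that
restriction/exonuclease circle selection exploits.

The simulated genome mimics the parts of a budding-yeast genome that matter
for extrachromosomal circular DNA (eccDNA) work:

* linear chromosomes of i.i.d. random background sequence;
* a copper-gene-like tandem array (head-to-tail repeats of a single unit,
  the substrate of homologous-recombination circle excision);
* an rDNA-like tandem array whose unit carries recognition sites for every
  panel enzyme (so rDNA circles are always destroyed by digestion);
* a separate high-copy circular episome ("2-micron") carried as an extra
  contig, cut by the standard panel but spared by the SmaI variant so it can
  anchor cross-sample normalization;
* subtelomeric, retrotransposon-like and ubiquitin-ligase-like regions that
  emit further circle species or must be excluded from quantification.

Coordinates are 0-based half-open everywhere; BED export follows the BED
convention. Recognition sites are treated as blunt single-position cuts at
the motif start. Degenerate bases never match a motif.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConstraintError, InputError, ParseError

# Standard REBASE recognition sequences (all palindromic, so a forward-strand
# scan finds every cut site).
DEFAULT_ENZYMES: dict[str, str] = {
    "EagI": "CGGCCG",
    "PvuI": "CGATCG",
    "PvuII": "CAGCTG",
    "SmaI": "CCCGGG",
    "EcoRI": "GAATTC",
    "XhoI": "CTCGAG",
}

VALID_LABELS = frozenset(
    {
        "tandem_array",
        "rDNA_like",
        "two_micron",
        "Ty_like",
        "subtelomere",
        "UBC9_like",
        "unique",
    }
)

#: feature labels considered repetitive when counting "nonrepetitive
#: chromosomal" fragments for scaling-factor denominators.
REPEAT_LABELS = frozenset(
    {"tandem_array", "rDNA_like", "Ty_like", "subtelomere", "two_micron"}
)

_BASES = "ACGT"
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = str.maketrans("ACGTN", "TGCAN")


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.uint8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


def decode_sequence(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return np.asarray(lut)[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Contig:
    """A named DNA sequence with fixed topology (``linear`` or ``circular``)."""

    name: str
    sequence: str
    topology: str = "linear"

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise InputError(f"contig {self.name!r}: empty sequence")
        if self.topology not in ("linear", "circular"):
            raise InputError(f"contig {self.name!r}: bad topology {self.topology!r}")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise InputError(f"contig {self.name!r}: invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FeatureAnnotation:
    """A labelled half-open interval on a contig.

    ``unit_length`` is set for tandem arrays (length of the repeated unit) and
    for circle-emitting regions (the whole region); it is carried in memory
    only and is not part of the BED representation.
    """

    contig: str
    start: int
    end: int
    label: str
    unit_length: int | None = None

    def __post_init__(self):
        if self.label not in VALID_LABELS:
            raise InputError(f"unknown feature label {self.label!r}")
        if not (0 <= self.start < self.end):
            raise InputError(
                f"feature {self.label} on {self.contig}: bad interval "
                f"[{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ArraySpec:
    """A tandem array: ``copies`` exact head-to-tail repeats of one unit."""

    contig: str
    start: int
    unit_length: int
    copies: int
    label: str = "tandem_array"
    contains: tuple[str, ...] = ()  # enzyme names whose motif must occur in the unit
    lacks: tuple[str, ...] = ()  # enzyme names whose motif is scrubbed from the unit


@dataclass(frozen=True)
class RegionSpec:
    """A single-copy circle-emitting or excluded region."""

    contig: str
    start: int
    length: int
    label: str = "subtelomere"
    contains: tuple[str, ...] = ()
    lacks: tuple[str, ...] = ()


@dataclass(frozen=True)
class CircularContigSpec:
    """An extra circular contig (the 2-micron-like episome)."""

    name: str
    length: int
    label: str = "two_micron"
    contains: tuple[str, ...] = ()
    lacks: tuple[str, ...] = ()


@dataclass(frozen=True)
class GenomeSpec:
    """Full recipe for a synthetic reference; same spec + seed is byte-reproducible."""

    seed: int = 0
    chromosomes: tuple[tuple[str, int], ...] = ()
    arrays: tuple[ArraySpec, ...] = ()
    regions: tuple[RegionSpec, ...] = ()
    circular_contigs: tuple[CircularContigSpec, ...] = ()
    enzymes: tuple[tuple[str, str], ...] = tuple(DEFAULT_ENZYMES.items())

    @property
    def enzyme_motifs(self) -> dict[str, str]:
        return dict(self.enzymes)

    def validate(self) -> None:
        motifs = self.enzyme_motifs
        for name, motif in motifs.items():
            if len(motif) < 4 or set(motif) - set(_BASES):
                raise ConstraintError(f"enzyme {name!r}: invalid motif {motif!r}")
        lengths = dict(self.chromosomes)
        for a in self.arrays:
            if a.copies < 1:
                raise ConstraintError("array copy number must be >= 1")
            if a.unit_length < 200:
                raise ConstraintError("repeat unit length must be >= 200 bp")
            if a.contig not in lengths:
                raise ConstraintError(f"array on unknown contig {a.contig!r}")
            if a.start + a.unit_length * a.copies > lengths[a.contig]:
                raise ConstraintError(f"array on {a.contig} exceeds contig length")
            _check_motif_constraints(a.unit_length, a.contains, a.lacks, motifs)
        for r in self.regions:
            if r.contig not in lengths:
                raise ConstraintError(f"region on unknown contig {r.contig!r}")
            if r.start + r.length > lengths[r.contig]:
                raise ConstraintError(f"region on {r.contig} exceeds contig length")
            _check_motif_constraints(r.length, r.contains, r.lacks, motifs)
        for c in self.circular_contigs:
            _check_motif_constraints(c.length, c.contains, c.lacks, motifs)
        # same-label features must not overlap
        feats: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for a in self.arrays:
            feats.setdefault((a.contig, a.label), []).append(
                (a.start, a.start + a.unit_length * a.copies)
            )
        for r in self.regions:
            feats.setdefault((r.contig, r.label), []).append((r.start, r.start + r.length))
        for (contig, label), ivs in feats.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ConstraintError(
                        f"overlapping {label} features on {contig}: "
                        f"[{s1},{e1}) and [{s2},{e2})"
                    )


def _check_motif_constraints(unit_length, contains, lacks, motifs):
    for name in tuple(contains) + tuple(lacks):
        if name not in motifs:
            raise ConstraintError(f"unknown enzyme {name!r} in constraint")
    overlap = set(contains) & set(lacks)
    if overlap:
        raise ConstraintError(f"enzymes both required and forbidden: {sorted(overlap)}")
    required = [motifs[n] for n in contains]
    if sum(len(m) for m in required) + len(required) > unit_length:
        raise ConstraintError("required motifs do not fit in the unit")
    for req in required:
        for forb_name in lacks:
            if motifs[forb_name] in req or req in motifs[forb_name]:
                raise ConstraintError(
                    f"required motif {req!r} collides with forbidden "
                    f"motif of {forb_name!r}"
                )


def find_recognition_sites(sequence: str, motif: str, topology: str = "linear") -> list[int]:
    """Start positions of exact motif matches, sorted, 0-based.

    For circular topology, matches spanning the end/start junction are
    reported modulo the sequence length. Overlapping matches are all
    reported. ``N`` never matches.
    """
    if not motif:
        raise InputError("empty motif")
    if set(motif) - set(_BASES):
        raise InputError(f"motif {motif!r} contains non-ACGT characters")
    if set(sequence) - set("ACGTN"):
        raise InputError("sequence contains invalid characters")
    if topology not in ("linear", "circular"):
        raise InputError(f"bad topology {topology!r}")
    n = len(sequence)
    if topology == "circular":
        if len(motif) > n:
            raise InputError("motif longer than circular sequence")
        scan = sequence + sequence[: len(motif) - 1]
    else:
        scan = sequence
    out = []
    pos = scan.find(motif)
    while pos != -1:
        out.append(pos % n if topology == "circular" else pos)
        pos = scan.find(motif, pos + 1)
    return sorted(set(out))


def has_site(sequence: str, motif: str, topology: str = "linear") -> bool:
    return bool(find_recognition_sites(sequence, motif, topology))


@dataclass
class Reference:
    """A built reference: contigs plus feature annotations."""

    contigs: list[Contig]
    features: list[FeatureAnnotation]
    spec: GenomeSpec | None = None
    _by_name: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._by_name = {c.name: c for c in self.contigs}

    def contig(self, name: str) -> Contig:
        return self._by_name[name]

    def contig_names(self) -> list[str]:
        return [c.name for c in self.contigs]

    def features_by_label(self, label: str) -> list[FeatureAnnotation]:
        return [f for f in self.features if f.label == label]

    @property
    def enzyme_motifs(self) -> dict[str, str]:
        if self.spec is not None:
            return self.spec.enzyme_motifs
        return dict(DEFAULT_ENZYMES)


def _generate_unit(
    length: int,
    contains: Sequence[str],
    lacks: Sequence[str],
    motifs: Mapping[str, str],
    rng: np.random.Generator,
) -> str:
    """Random unit with required motifs planted and forbidden motifs scrubbed.

    Scrubbing treats the unit as circular so that forbidden motifs are also
    absent across head-to-tail junctions of tandem copies and across the
    junction of a circle made from the unit.
    """
    codes = rng.integers(0, 4, size=length).astype(np.uint8)
    protected = np.zeros(length, dtype=bool)
    required = [motifs[n] for n in contains]
    if required:
        # plant evenly spaced
        gap = length // len(required)
        for i, m in enumerate(required):
            p = (i * gap + gap // 4) % length
            if p + len(m) > length:  # keep planted motifs off the junction
                p = length - len(m)
            codes[p : p + len(m)] = encode_sequence(m)
            protected[p : p + len(m)] = True
    forbidden = [motifs[n] for n in lacks]
    for _ in range(20 * length + 100):
        seq = decode_sequence(codes)
        hit = None
        for m in forbidden:
            sites = find_recognition_sites(seq, m, "circular")
            if sites:
                hit = (sites[0], len(m))
                break
        if hit is None:
            return seq
        p, mlen = hit
        idx = [(p + j) % length for j in range(mlen) if not protected[(p + j) % length]]
        if not idx:
            raise ConstraintError(
                "forbidden motif fully inside a required motif; constraints collide"
            )
        j = idx[rng.integers(0, len(idx))]
        codes[j] = (codes[j] + 1 + rng.integers(0, 3)) % 4
    raise ConstraintError("could not scrub forbidden motifs (constraints too tight)")


def build_reference(spec: GenomeSpec) -> Reference:
    """Build the synthetic reference described by ``spec``.

    Identical spec + seed reproduce byte-identical sequences. Chance
    occurrences of enzyme motifs in background sequence are permitted and not
    scrubbed; only declared constraints are enforced.
    """
    spec.validate()
    motifs = spec.enzyme_motifs
    rng = np.random.default_rng(spec.seed)
    contigs: list[Contig] = []
    features: list[FeatureAnnotation] = []
    placements: dict[str, list] = {name: [] for name, _ in spec.chromosomes}
    for a in spec.arrays:
        placements[a.contig].append(a)
    for r in spec.regions:
        placements[r.contig].append(r)
    for name, length in spec.chromosomes:
        codes = rng.integers(0, 4, size=length).astype(np.uint8)
        for item in sorted(placements[name], key=lambda x: x.start):
            if isinstance(item, ArraySpec):
                unit = _generate_unit(item.unit_length, item.contains, item.lacks, motifs, rng)
                tiled = encode_sequence(unit * item.copies)
                end = item.start + len(tiled)
                codes[item.start : end] = tiled
                features.append(
                    FeatureAnnotation(name, item.start, end, item.label, item.unit_length)
                )
            else:
                seg = _generate_unit(item.length, item.contains, item.lacks, motifs, rng)
                end = item.start + item.length
                codes[item.start : end] = encode_sequence(seg)
                features.append(
                    FeatureAnnotation(name, item.start, end, item.label, item.length)
                )
        contigs.append(Contig(name, decode_sequence(codes), "linear"))
    for c in spec.circular_contigs:
        seq = _generate_unit(c.length, c.contains, c.lacks, motifs, rng)
        contigs.append(Contig(c.name, seq, "circular"))
        features.append(FeatureAnnotation(c.name, 0, c.length, c.label, c.length))
    return Reference(contigs, features, spec)


def default_genome_spec(seed: int = 0) -> GenomeSpec:
    """A yeast-like default reference (~160 kb, scaled down ~80x).

    chrI carries a copper-array-like locus (2 kb unit x 9 copies, unit free of
    all candidate panel motifs so its circles always survive selection) and a
    small excluded ubiquitin-ligase-like locus; chrII carries two
    retrotransposon-like regions; chrIII carries an rDNA-like array whose unit
    contains a site for every candidate enzyme. Subtelomeric circle-emitting
    regions sit at every chromosome end and are scrubbed of EagI sites only,
    so those circles survive one reaction in three. The circular episome
    contains EagI/PvuI/PvuII sites but no SmaI site, mirroring the enzyme
    choice that spares it for normalization.
    """
    panel_all = ("EagI", "PvuI", "PvuII", "SmaI")
    sub = lambda contig, start: RegionSpec(contig, start, 4000, "subtelomere", (), ("EagI",))
    return GenomeSpec(
        seed=seed,
        chromosomes=(("chrI", 60000), ("chrII", 50000), ("chrIII", 40000)),
        arrays=(
            ArraySpec("chrI", 20000, 2000, 9, "tandem_array", (), panel_all),
            ArraySpec("chrIII", 10000, 3000, 5, "rDNA_like", panel_all, ()),
        ),
        regions=(
            sub("chrI", 0),
            sub("chrI", 56000),
            sub("chrII", 0),
            sub("chrII", 46000),
            sub("chrIII", 0),
            sub("chrIII", 36000),
            RegionSpec("chrII", 20000, 6000, "Ty_like", (), ("EagI",)),
            RegionSpec("chrII", 32000, 6000, "Ty_like", (), ("EagI",)),
            RegionSpec("chrI", 45000, 600, "UBC9_like", (), ("EagI",)),
        ),
        circular_contigs=(
            CircularContigSpec("two_micron", 6300, "two_micron", ("EagI", "PvuI", "PvuII"), ("SmaI",)),
        ),
    )


# ---------------------------------------------------------------------------
# External formats


def write_fasta(contigs: Iterable[Contig], path) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.name, description=f"topology={c.topology}")
        for c in contigs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[Contig]:
    contigs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        topology = "circular" if "topology=circular" in rec.description else "linear"
        contigs.append(Contig(rec.id, str(rec.seq).upper(), topology))
    return contigs


def write_bed(features: Iterable[FeatureAnnotation], path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.contig}\t{f.start}\t{f.end}\t{f.label}\t0\t+\n")


def read_bed(path) -> list[FeatureAnnotation]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected >=4 BED columns")
            try:
                out.append(
                    FeatureAnnotation(parts[0], int(parts[1]), int(parts[2]), parts[3])
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_enzyme_table(motifs: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("enzyme\tmotif\n")
        for name, motif in motifs.items():
            fh.write(f"{name}\t{motif}\n")


def read_enzyme_table(path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("enzyme"):
            raise ParseError(f"{path}:1: expected 'enzyme\\tmotif' header")
        for lineno, line in enumerate(fh, 2):
            line = line.strip()
            if not line:
                continue
            try:
                name, motif = line.split("\t")
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: expected 2 columns") from exc
            out[name] = motif
    return out
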