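"""In-silico REC-seq library construction.

REC-seq enriches circular DNA by splitting a sample into three reactions,
cutting with a different restriction enzyme in each, destroying everything
linear with exonucleases (ExoV degrades linear double-stranded DNA from its
ends; circles are resistant), and reuniting the reactions. A circle survives
iff it lacks a recognition site for at least one panel enzyme; with complete
digestion its surviving weight is (number of site-free enzymes)/3 of the
input. Nuisance circles (rDNA circles, the 2-micron episome) carry sites for
every panel enzyme and are eliminated; in the SmaI panel variant one enzyme
deliberately spares the episome so it can anchor cross-sample normalization.

This module provides the molecule-level operations (excision, digestion,
exonuclease selection, the full two-round protocol), an enzyme-panel
designer, and a paired-end read generator with truth tags.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import genome as _genome
from .errors import DesignInfeasibleError, InputError
from .genome import (
    Contig,
    FeatureAnnotation,
    Reference,
    decode_sequence,
    encode_sequence,
    find_recognition_sites,
)


@dataclass(frozen=True)
class CircularSpecies:
    """One circular DNA species with a per-cell-equivalent abundance."""

    id: str
    source_contig: str
    span: tuple[int, int]  # half-open coordinates on the source contig
    sequence: str
    abundance: float = 1.0
    topology: str = "circular"

    def __post_init__(self):
        if self.abundance < 0:
            raise InputError("abundance must be >= 0")


@dataclass(frozen=True)
class Molecule:
    sequence: str
    topology: str = "linear"
    provenance: str = "chromosomal"

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise InputError("empty molecule")

    def __len__(self):
        return len(self.sequence)


class MoleculePool:
    """Weighted collection of molecules (weight = copies per cell-equivalent)."""

    def __init__(self, entries: Iterable[tuple[Molecule, float]] = ()):
        self.entries: list[tuple[Molecule, float]] = []
        for mol, w in entries:
            self.add(mol, w)

    def add(self, molecule: Molecule, weight: float) -> None:
        if weight < 0 or not np.isfinite(weight):
            raise InputError("weights must be finite and >= 0")
        self.entries.append((molecule, float(weight)))

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def total_weight(self) -> float:
        return sum(w for _, w in self.entries)

    def weight_by_provenance(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for mol, w in self.entries:
            out[mol.provenance] = out.get(mol.provenance, 0.0) + w
        return out


@dataclass(frozen=True)
class EnzymePanel:
    """Ordered triple of (enzyme name, recognition motif)."""

    enzymes: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if len(self.enzymes) != 3:
            raise InputError("a panel holds exactly 3 enzymes")
        names = [n for n, _ in self.enzymes]
        if len(set(names)) != 3:
            raise InputError("panel enzymes must be distinct")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.enzymes)

    @property
    def motifs(self) -> tuple[str, ...]:
        return tuple(m for _, m in self.enzymes)


def panel_from_names(names: Sequence[str], motifs: Mapping[str, str] | None = None) -> EnzymePanel:
    motifs = dict(motifs or _genome.DEFAULT_ENZYMES)
    return EnzymePanel(tuple((n, motifs[n]) for n in names))


def excise_species(
    reference: Reference,
    feature: FeatureAnnotation,
    n_units: int,
    start_unit: int = 0,
    abundance: float = 1.0,
) -> CircularSpecies:
    """Excise a circle of ``n_units`` consecutive repeat units from an array.

    For single-copy circle-emitting regions (subtelomeres, retrotransposon
    loci...) the whole feature is one "unit". The circle junction falls on a
    unit boundary, mirroring excision by homologous recombination between
    repeats.
    """
    if feature.unit_length is None:
        raise InputError(f"feature {feature.label} has no unit length; cannot excise")
    unit = feature.unit_length
    copies = len(feature) // unit
    if n_units < 1 or start_unit < 0 or start_unit + n_units > copies:
        raise InputError(
            f"units [{start_unit}, {start_unit + n_units}) outside array of {copies} copies"
        )
    s = feature.start + start_unit * unit
    e = s + n_units * unit
    seq = reference.contig(feature.contig).sequence[s:e]
    return CircularSpecies(
        id=f"{feature.label}:{feature.contig}:{feature.start}:u{start_unit}+{n_units}",
        source_contig=feature.contig,
        span=(s, e),
        sequence=seq,
        abundance=abundance,
    )


def species_molecule(sp: CircularSpecies) -> Molecule:
    return Molecule(sp.sequence, "circular", sp.id)


def digest(
    molecule: Molecule,
    motif: str,
    p_cut: float = 1.0,
    rng: np.random.Generator | None = None,
) -> list[Molecule]:
    """Cut each recognition site independently with probability ``p_cut``.

    Cuts are blunt single-position cuts at the motif start. A circle with k>=1
    realized cuts yields k linear fragments whose lengths sum to the circle
    length; with 0 cuts it stays circular. A linear molecule with k cuts
    yields k+1 fragments.
    """
    if not 0.0 <= p_cut <= 1.0:
        raise InputError("p_cut must be in [0, 1]")
    sites = find_recognition_sites(molecule.sequence, motif, molecule.topology)
    if p_cut < 1.0:
        if rng is None:
            rng = np.random.default_rng()
        sites = [s for s in sites if rng.random() < p_cut]
    seq, prov = molecule.sequence, molecule.provenance
    n = len(seq)
    if molecule.topology == "circular":
        if not sites:
            return [molecule]
        frags = []
        for a, b in zip(sites, sites[1:] + [sites[0] + n]):
            frag = seq[a:b] if b <= n else seq[a:] + seq[: b - n]
            frags.append(Molecule(frag, "linear", prov))
        return frags
    cuts = [0] + [s for s in sites if 0 < s < n] + [n]
    return [Molecule(seq[a:b], "linear", prov) for a, b in zip(cuts, cuts[1:]) if b > a]


def exonuclease_select(pool: MoleculePool) -> MoleculePool:
    """Remove all linear molecules; circles pass untouched. Idempotent."""
    return MoleculePool((m, w) for m, w in pool if m.topology == "circular")


def run_recseq(
    pool: MoleculePool,
    panel: EnzymePanel,
    rounds: int = 2,
    p_cut: float = 1.0,
    seed: int | None = None,
) -> MoleculePool:
    """Run the split/digest/exonuclease/reunite protocol.

    The pool is split into 3 equal-weight aliquots; aliquot i undergoes
    ``rounds`` cycles of digestion with enzyme i followed by exonuclease
    selection; aliquots are then reunited. With ``p_cut=1`` a species
    survives iff it lacks sites for at least one panel enzyme, with weight
    (site-free enzymes)/3 of its input.
    """
    rng = np.random.default_rng(seed)
    out = MoleculePool()
    for name, motif in panel.enzymes:
        aliquot = [(m, w / 3.0) for m, w in pool]
        for _ in range(rounds):
            digested: list[tuple[Molecule, float]] = []
            for mol, w in aliquot:
                for frag in digest(mol, motif, p_cut, rng):
                    digested.append((frag, w))
            aliquot = [(m, w) for m, w in digested if m.topology == "circular"]
        for mol, w in aliquot:
            out.add(mol, w)
    return out


def survives_complete_digestion(sequence: str, panel: EnzymePanel) -> tuple[bool, int]:
    """Brute-force survival rule for a circle under complete digestion.

    Returns (survives, number of site-free panel enzymes).
    """
    free = sum(
        0 if find_recognition_sites(sequence, motif, "circular") else 1
        for motif in panel.motifs
    )
    return free > 0, free


def choose_enzyme_panel(
    nuisance_species: Sequence[CircularSpecies],
    target_species: Sequence[CircularSpecies],
    candidates: Mapping[str, str],
    spare: CircularSpecies | None = None,
) -> EnzymePanel:
    """Pick 3 enzymes cutting every nuisance circle while sparing every target.

    Every nuisance species must have >= 1 site for *every* panel enzyme (so it
    is destroyed in all three reactions) and every target species must lack
    sites for >= 1 enzyme (so it survives at least one reaction). If ``spare``
    is given, at least one panel enzyme must have zero sites in it, and such
    an enzyme is placed in the last panel slot (the normalization-anchor
    reaction). Ties are broken by lexicographic enzyme-name order.
    """
    if len(candidates) < 3:
        raise InputError("need at least 3 candidate enzymes")
    names = sorted(candidates)
    cuts: dict[str, dict[str, bool]] = {}  # enzyme -> species id -> has site
    specials = list(nuisance_species) + list(target_species) + ([spare] if spare else [])
    for n in names:
        cuts[n] = {
            sp.id: bool(find_recognition_sites(sp.sequence, candidates[n], "circular"))
            for sp in specials
        }
    best, best_score, needed = None, -1, 0
    for triple in itertools.combinations(names, 3):
        score = 0
        n_constraints = 0
        for sp in nuisance_species:
            n_constraints += 1
            score += all(cuts[n][sp.id] for n in triple)
        for sp in target_species:
            n_constraints += 1
            score += any(not cuts[n][sp.id] for n in triple)
        sparing = [n for n in triple if spare is not None and not cuts[n][spare.id]]
        if spare is not None:
            n_constraints += 1
            score += bool(sparing)
        needed = n_constraints
        if score > best_score:
            best_score, best = score, (triple, sparing)
        if score == n_constraints:
            triple, sparing = best
            if spare is not None:
                ordered = [n for n in triple if n not in sparing[:1]] + sparing[:1]
            else:
                ordered = list(triple)
            return EnzymePanel(tuple((n, candidates[n]) for n in ordered))
    raise DesignInfeasibleError(
        f"no valid enzyme triple; best partial cover {best[0]} satisfies "
        f"{best_score}/{needed} constraints",
        best_partial=best[0] if best else None,
    )


# ---------------------------------------------------------------------------
# Read generation


class ReadPairSet:
    """Paired-end reads as code arrays, with per-pair truth tags.

    ``seq1``/``seq2`` are (n, read_length) uint8 arrays (A=0..T=3); ``source``
    indexes into ``sources`` (species id or "chromosomal:<contig>").
    """

    def __init__(self, seq1, seq2, source, sources, read_length):
        self.seq1 = np.asarray(seq1, dtype=np.uint8)
        self.seq2 = np.asarray(seq2, dtype=np.uint8)
        self.source = np.asarray(source, dtype=np.int32)
        self.sources = list(sources)
        self.read_length = int(read_length)

    def __len__(self):
        return self.seq1.shape[0]

    def source_labels(self) -> np.ndarray:
        return np.asarray(self.sources, dtype=object)[self.source]

    def mate_strings(self, i: int) -> tuple[str, str]:
        return decode_sequence(self.seq1[i]), decode_sequence(self.seq2[i])

    def to_fastq(self, path1, path2, prefix: str = "sim") -> None:
        """Write the pair set as FASTQ (gzipped when the path ends in .gz).

        Gzip streams are written with a zeroed timestamp so identical runs
        produce byte-identical files.
        """
        for path, seqs, mate in ((path1, self.seq1, 1), (path2, self.seq2, 2)):
            qual = "I" * self.read_length
            if str(path).endswith(".gz"):
                import io

                raw = open(path, "wb")
                gz = gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0)
                fh = io.TextIOWrapper(gz, encoding="ascii")
            else:
                raw = gz = None
                fh = open(path, "wt")
            try:
                for i in range(len(self)):
                    fh.write(
                        f"@{prefix}:{i:07d} src={self.sources[self.source[i]]}/{mate}\n"
                        f"{decode_sequence(seqs[i])}\n+\n{qual}\n"
                    )
            finally:
                fh.close()
                if raw is not None:
                    raw.close()

    @classmethod
    def from_fastq(cls, path1, path2):
        from Bio import SeqIO

        def load(path):
            opener = gzip.open if str(path).endswith(".gz") else open
            ids, seqs = [], []
            with opener(path, "rt") as fh:
                for rec in SeqIO.parse(fh, "fastq"):
                    src = "unknown"
                    for tok in rec.description.split():
                        if tok.startswith("src="):
                            src = tok[4:].rsplit("/", 1)[0]
                    ids.append(src)
                    seqs.append(str(rec.seq).upper())
            return ids, seqs

        src1, s1 = load(path1)
        src2, s2 = load(path2)
        if len(s1) != len(s2):
            raise InputError("mate files differ in read count")
        if not s1:
            return cls(
                np.zeros((0, 0), np.uint8), np.zeros((0, 0), np.uint8), [], [], 0
            )
        rl = len(s1[0])
        sources = sorted(set(src1))
        lut = {s: i for i, s in enumerate(sources)}
        seq1 = np.stack([encode_sequence(s) for s in s1])
        seq2 = np.stack([encode_sequence(s) for s in s2])
        return cls(seq1, seq2, [lut[s] for s in src1], sources, rl)


def generate_reads(
    pool: MoleculePool,
    depth: int,
    read_length: int = 75,
    insert_mean: float = 300.0,
    insert_sd: float = 60.0,
    insert_min: int = 100,
    insert_max: int = 700,
    error_rate: float = 0.001,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ReadPairSet:
    """Draw ``depth`` paired-end reads from a molecule pool.

    Fragments are drawn from molecules proportional to weight x length
    (uniform random shearing); insert lengths are Normal(mean, sd) rounded
    and clipped to [insert_min, insert_max] and to the molecule length.
    Circular molecules may yield junction-spanning fragments. Mate 1 is the
    5' ``read_length`` of the fragment; mate 2 is the reverse complement of
    the 3' end. Substitution errors are applied per base at ``error_rate``.
    """
    if depth < 1:
        raise InputError("depth must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    mols = [(m, w) for m, w in pool if w > 0 and len(m) >= read_length]
    if not mols:
        raise InputError("empty pool (no weighted molecule long enough to sequence)")
    weights = np.array([w * len(m) for m, w in mols], dtype=float)
    counts = rng.multinomial(depth, weights / weights.sum())
    sources: list[str] = []
    src_idx: dict[str, int] = {}
    seq1 = np.empty((depth, read_length), dtype=np.uint8)
    seq2 = np.empty((depth, read_length), dtype=np.uint8)
    source = np.empty(depth, dtype=np.int32)
    ar = np.arange(read_length)
    row = 0
    for (mol, _w), n in zip(mols, counts):
        if n == 0:
            continue
        codes = encode_sequence(mol.sequence)
        L = len(codes)
        lab = mol.provenance
        if lab not in src_idx:
            src_idx[lab] = len(sources)
            sources.append(lab)
        ins = np.rint(rng.normal(insert_mean, insert_sd, size=n)).astype(np.int64)
        ins = np.clip(ins, max(insert_min, read_length), min(insert_max, L))
        if mol.topology == "circular":
            starts = rng.integers(0, L, size=n)
            i1 = (starts[:, None] + ar[None, :]) % L
            i2 = (starts[:, None] + (ins - read_length)[:, None] + ar[None, :]) % L
        else:
            starts = (rng.random(n) * (L - ins + 1)).astype(np.int64)
            i1 = starts[:, None] + ar[None, :]
            i2 = (starts + ins - read_length)[:, None] + ar[None, :]
        seq1[row : row + n] = codes[i1]
        seq2[row : row + n] = (3 - codes[i2])[:, ::-1]
        source[row : row + n] = src_idx[lab]
        row += n
    assert row == depth
    if error_rate > 0:
        for arr in (seq1, seq2):
            mask = rng.random(arr.shape) < error_rate
            shifts = rng.integers(1, 4, size=int(mask.sum()))
            arr[mask] = (arr[mask] + shifts) % 4
    return ReadPairSet(seq1, seq2, source, sources, read_length)


def build_library_pool(
    reference: Reference,
    species: Sequence[CircularSpecies],
    mode: str,
    panel: EnzymePanel | None = None,
    rounds: int = 2,
    p_cut: float = 1.0,
    background_weight: float = 1.0,
    leak_fraction: float = 0.001,
    seed: int | None = None,
) -> MoleculePool:
    """Assemble the molecule pool for one library.

    ``total``: chromosomal contigs at ``background_weight`` plus every circle
    at its abundance (no selection). ``exo_only``: exonuclease selection with
    no digestion; ``recseq``: the full split/digest/select protocol. In both
    selected modes the chromosomal background is retained at
    ``leak_fraction * background_weight`` to mimic incomplete exonuclease
    digestion.
    """
    chrom = [
        (Molecule(c.sequence, c.topology, f"chromosomal:{c.name}"), background_weight)
        for c in reference.contigs
        if c.topology == "linear"
    ]
    circles = MoleculePool((species_molecule(sp), sp.abundance) for sp in species)
    if mode == "total":
        pool = MoleculePool(chrom)
        for m, w in circles:
            pool.add(m, w)
        return pool
    if mode == "exo_only":
        pool = exonuclease_select(circles)
    elif mode == "recseq":
        if panel is None:
            raise InputError("recseq mode needs an enzyme panel")
        pool = run_recseq(circles, panel, rounds=rounds, p_cut=p_cut, seed=seed)
    else:
        raise InputError(f"unknown library mode {mode!r}")
    for mol, w in chrom:
        pool.add(mol, w * leak_fraction)
    return pool
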