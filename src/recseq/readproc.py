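"""Read mapping and the two deduplication passes.

The built-in mapper replaces an external short-read aligner for synthetic
data: it seeds each mate with its first 31-mer in a reference k-mer index,
extends to full length allowing a bounded number of substitutions, and
reports a pair only when both mates map at a unique best score in convergent
orientation on one contig with an outer span within the insert bound. Pairs
with one unmapped or ambiguous mate are discarded entirely (no singleton
reporting), mirroring stringent paired-end alignment settings used to avoid
apparent enrichment of repeats by multi-mapping.

The one deliberate exception concerns tandem arrays: mates whose tied best
hits all fall on the *same* repeat array, congruent modulo the unit length,
are assigned to the leftmost tied unit and flagged ``multi_unit`` — array
units are identical by construction, so per-unit resolution is not claimed
but within-array fragments must not be thrown away.

Deduplication follows the two-pass scheme used for circle-sequencing data:
first by exact sequence identity of the first 50 bp of both mates (on the
raw read sequences), then by alignment position (contig, fragment start,
fragment end). Both passes keep the first occurrence in input order and are
idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

from .errors import InputError, ParseError
from .genome import Reference, decode_sequence
from .libsim import ReadPairSet

_PAD = 512  # sentinel gap between/after contigs; must exceed the read length


def _void_view(arr: np.ndarray) -> np.ndarray:
    a = np.ascontiguousarray(arr)
    return a.view(np.dtype((np.void, a.dtype.itemsize * a.shape[1]))).ravel()


def _first_occurrence_mask(keys: np.ndarray) -> np.ndarray:
    """Boolean mask keeping the first occurrence of each distinct row key."""
    _, first = np.unique(keys, return_index=True)
    mask = np.zeros(len(keys), dtype=bool)
    mask[first] = True
    return mask


class GenomeIndex:
    """Exact k-mer index over the concatenated (linearized) reference."""

    def __init__(self, reference: Reference, seed_length: int = 31):
        if seed_length < 8 or seed_length > 31:
            raise InputError("seed length must be in [8, 31]")
        self.seed_length = seed_length
        self.contig_names = reference.contig_names()
        segments, offsets = [], []
        from .genome import encode_sequence

        pos = 0
        for c in reference.contigs:
            offsets.append(pos)
            segments.append(encode_sequence(c.sequence))
            segments.append(np.full(_PAD, 4, dtype=np.uint8))
            pos += len(c.sequence) + _PAD
        self.codes = np.concatenate(segments)
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.lengths = np.asarray([len(c.sequence) for c in reference.contigs], np.int64)
        k = seed_length
        self._pow = (4 ** np.arange(k - 1, -1, -1, dtype=np.uint64))
        win = np.lib.stride_tricks.sliding_window_view(self.codes, k)
        valid = (win <= 3).all(axis=1)
        hashes = (win.astype(np.uint64) * self._pow[None, :]).sum(axis=1)
        positions = np.nonzero(valid)[0].astype(np.int64)
        hashes = hashes[valid]
        order = np.argsort(hashes, kind="stable")
        self.hashes = hashes[order]
        self.positions = positions[order]
        # repeat arrays whose tiled units are identical (tie-resolution targets)
        arrs = [
            f
            for f in reference.features
            if f.label in ("tandem_array", "rDNA_like") and f.unit_length
        ]
        name_to_i = {n: i for i, n in enumerate(self.contig_names)}
        arrs.sort(key=lambda f: self.offsets[name_to_i[f.contig]] + f.start)
        self.arr_gstart = np.asarray(
            [self.offsets[name_to_i[f.contig]] + f.start for f in arrs], np.int64
        )
        self.arr_gend = np.asarray(
            [self.offsets[name_to_i[f.contig]] + f.end for f in arrs], np.int64
        )
        self.arr_unit = np.asarray([f.unit_length for f in arrs], np.int64)

    def seed_hash(self, codes: np.ndarray) -> np.ndarray:
        return (codes[:, : self.seed_length].astype(np.uint64) * self._pow[None, :]).sum(
            axis=1
        )

    def contig_of(self, gpos: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.offsets, gpos, side="right") - 1


def _flat_ranges(lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expand [lo_i, hi_i) ranges; returns (owner row, flat index)."""
    cnt = hi - lo
    total = int(cnt.sum())
    owner = np.repeat(np.arange(len(lo)), cnt)
    if total == 0:
        return owner, np.empty(0, dtype=np.int64)
    nz = cnt > 0
    l, c = lo[nz], cnt[nz]
    starts = np.concatenate(([0], np.cumsum(c)[:-1]))
    flat = np.arange(total, dtype=np.int64) - np.repeat(starts, c) + np.repeat(l, c)
    return owner, flat


@dataclass
class _MateResolution:
    ok: np.ndarray
    strand: np.ndarray  # 0 forward, 1 reverse
    pos_left: np.ndarray  # leftmost tied global position (== position if untied)
    pos_right: np.ndarray
    unit: np.ndarray  # array unit length for tied mates; 1 otherwise
    tied: np.ndarray


def _resolve_mate(
    codes: np.ndarray, index: GenomeIndex, max_mismatches: int, chunk: int = 200_000
) -> _MateResolution:
    N, L = codes.shape
    rc = np.where(codes <= 3, 3 - codes, 4)[:, ::-1].astype(np.uint8)
    cand_r, cand_p, cand_s = [], [], []
    for oc, strand in ((codes, 0), (rc, 1)):
        h = index.seed_hash(oc)
        lo = np.searchsorted(index.hashes, h, side="left")
        hi = np.searchsorted(index.hashes, h, side="right")
        owner, flat = _flat_ranges(lo, hi)
        cand_r.append(owner)
        cand_p.append(index.positions[flat])
        cand_s.append(np.full(len(owner), strand, dtype=np.int8))
    cr = np.concatenate(cand_r)
    cp = np.concatenate(cand_p)
    cs = np.concatenate(cand_s)
    mm = np.empty(len(cr), dtype=np.int32)
    arL = np.arange(L)
    for a in range(0, len(cr), chunk):
        b = min(a + chunk, len(cr))
        win = index.codes[cp[a:b, None] + arL[None, :]]
        q = np.where(cs[a:b, None] == 0, codes[cr[a:b]], rc[cr[a:b]])
        mm[a:b] = (win != q).sum(axis=1)
    keep = mm <= max_mismatches
    cr, cp, cs, cm = cr[keep], cp[keep], cs[keep], mm[keep]
    best = np.full(N, 255, dtype=np.int32)
    np.minimum.at(best, cr, cm)
    sel = cm == best[cr]
    cr, cp, cs = cr[sel], cp[sel], cs[sel]
    nbest = np.bincount(cr, minlength=N)
    ok = nbest >= 1
    unique = nbest == 1
    pos_left = np.zeros(N, dtype=np.int64)
    pos_right = np.zeros(N, dtype=np.int64)
    strand = np.zeros(N, dtype=np.int8)
    unit = np.ones(N, dtype=np.int64)
    tied = np.zeros(N, dtype=bool)
    # unique mates: their single best row carries position and strand
    acc_p = np.zeros(N, dtype=np.int64)
    acc_s = np.zeros(N, dtype=np.int64)
    np.add.at(acc_p, cr, cp)
    np.add.at(acc_s, cr, cs.astype(np.int64))
    pos_left[unique] = acc_p[unique]
    pos_right[unique] = acc_p[unique]
    strand[unique] = acc_s[unique].astype(np.int8)
    # tied mates: allowed only when all tied hits sit on one repeat array,
    # congruent modulo the unit, on one strand
    multi = nbest[cr] > 1
    if multi.any() and len(index.arr_gstart):
        mr, mp, ms = cr[multi], cp[multi], cs[multi]
        ai = np.searchsorted(index.arr_gstart, mp, side="right") - 1
        aic = np.clip(ai, 0, None)
        in_arr = (ai >= 0) & (mp + L <= index.arr_gend[aic])
        off = np.where(in_arr, (mp - index.arr_gstart[aic]) % index.arr_unit[aic], -1)
        big = np.int64(1) << 60
        mins = {}
        maxs = {}
        for key, vals in (("a", aic), ("o", off), ("s", ms.astype(np.int64)), ("p", mp)):
            mn = np.full(N, big)
            mx = np.full(N, -big)
            np.minimum.at(mn, mr, vals)
            np.maximum.at(mx, mr, vals)
            mins[key], maxs[key] = mn, mx
        allin = np.ones(N, dtype=np.int64)
        np.minimum.at(allin, mr, in_arr.astype(np.int64))
        consistent = (
            ~unique
            & ok
            & (allin == 1)
            & (mins["a"] == maxs["a"])
            & (mins["o"] == maxs["o"])
            & (mins["s"] == maxs["s"])
        )
        pos_left[consistent] = mins["p"][consistent]
        pos_right[consistent] = maxs["p"][consistent]
        strand[consistent] = mins["s"][consistent].astype(np.int8)
        unit[consistent] = index.arr_unit[np.clip(mins["a"][consistent], 0, None)]
        tied[consistent] = True
        ok &= unique | consistent
    else:
        ok &= unique
    return _MateResolution(ok, strand, pos_left, pos_right, unit, tied)


@dataclass
class MappingStats:
    n_pairs: int = 0
    n_mapped: int = 0
    n_mate_unresolved: int = 0  # a mate unmapped or ambiguous
    n_improper: int = 0  # wrong orientation / contig / span


@dataclass
class DedupReport:
    pass_name: str
    n_input: int
    n_retained: int

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_retained


@dataclass
class FragmentSet:
    """Proper-pair fragments as parallel arrays (0-based half-open outer spans)."""

    contig_names: list[str]
    contig_index: np.ndarray
    start: np.ndarray
    end: np.ndarray
    multi_unit: np.ndarray
    m1_forward: np.ndarray
    key1: np.ndarray  # raw mate-1 prefix codes, (n, window)
    key2: np.ndarray
    read_index: np.ndarray
    stats: MappingStats | None = None

    def __len__(self):
        return len(self.start)

    def subset(self, idx) -> "FragmentSet":
        return FragmentSet(
            self.contig_names,
            self.contig_index[idx],
            self.start[idx],
            self.end[idx],
            self.multi_unit[idx],
            self.m1_forward[idx],
            self.key1[idx],
            self.key2[idx],
            self.read_index[idx],
            self.stats,
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "contig": np.asarray(self.contig_names, dtype=object)[self.contig_index],
                "start": self.start,
                "end": self.end,
                "multi_unit": self.multi_unit,
                "read_index": self.read_index,
            }
        )


def map_reads(
    reads: ReadPairSet,
    reference: Reference,
    max_insert: int = 2000,
    max_mismatches: int = 2,
    seed_length: int = 31,
    dedup_window: int = 50,
    index: GenomeIndex | None = None,
) -> FragmentSet:
    """Map paired reads to the reference with the built-in exact-seed mapper."""
    if index is None:
        index = GenomeIndex(reference, seed_length)
    N = len(reads)
    L = reads.read_length
    if L < index.seed_length:
        raise InputError("reads shorter than the seed length")
    r1 = _resolve_mate(reads.seq1, index, max_mismatches)
    r2 = _resolve_mate(reads.seq2, index, max_mismatches)
    both = r1.ok & r2.ok
    opposite = both & (r1.strand != r2.strand)
    m1fwd = r1.strand == 0

    def pick(a1, a2):
        return np.where(m1fwd, a1, a2)

    f_left = pick(r1.pos_left, r2.pos_left)
    f_right = pick(r1.pos_right, r2.pos_right)
    f_unit = pick(r1.unit, r2.unit)
    f_tied = np.where(m1fwd, r1.tied, r2.tied)
    b_left = pick(r2.pos_left, r1.pos_left)
    b_right = pick(r2.pos_right, r1.pos_right)
    b_unit = pick(r2.unit, r1.unit)
    b_tied = np.where(m1fwd, r2.tied, r1.tied)
    # forward mate: when tied and the reverse mate is not, take the largest
    # tied candidate left of the reverse mate (then report shifted to the
    # leftmost unit); otherwise the leftmost candidate.
    k_f = np.where(
        f_tied & ~b_tied,
        np.clip((b_left - f_left) // np.maximum(f_unit, 1), 0, (f_right - f_left) // np.maximum(f_unit, 1)),
        0,
    )
    p_f = f_left + k_f * f_unit
    # reverse mate: smallest tied candidate at or right of the forward mate
    k_b = np.where(
        b_tied,
        np.clip(-((b_left - p_f) // np.maximum(b_unit, 1)), 0, (b_right - b_left) // np.maximum(b_unit, 1)),
        0,
    )
    p_b = b_left + k_b * b_unit
    span = p_b + L - p_f
    ci_f = index.contig_of(p_f)
    ci_b = index.contig_of(p_b + L - 1)
    proper = opposite & (p_f <= p_b) & (span <= max_insert) & (ci_f == ci_b)
    start_g = np.where(f_tied, f_left, p_f)
    end_g = start_g + span
    stats = MappingStats(
        n_pairs=N,
        n_mapped=int(proper.sum()),
        n_mate_unresolved=int((~both).sum()),
        n_improper=int((both & ~proper).sum()),
    )
    idx = np.nonzero(proper)[0]
    w = min(dedup_window, L)
    if w < dedup_window:
        import warnings

        warnings.warn(f"reads shorter than {dedup_window} bp; dedup key uses full read")
    return FragmentSet(
        contig_names=list(index.contig_names),
        contig_index=ci_f[idx].astype(np.int32),
        start=(start_g[idx] - index.offsets[ci_f[idx]]).astype(np.int64),
        end=(end_g[idx] - index.offsets[ci_f[idx]]).astype(np.int64),
        multi_unit=(f_tied | b_tied)[idx],
        m1_forward=m1fwd[idx],
        key1=np.ascontiguousarray(reads.seq1[idx, :w]),
        key2=np.ascontiguousarray(reads.seq2[idx, :w]),
        read_index=idx.astype(np.int64),
        stats=stats,
    )


# ---------------------------------------------------------------------------
# Deduplication


def dedup_by_sequence(obj, window: int = 50):
    """Keep one pair per (mate-1 prefix, mate-2 prefix) key; first wins.

    Accepts a :class:`FragmentSet` (keys were captured from the raw reads at
    mapping time) or a :class:`ReadPairSet` (pre-alignment deduplication).
    Returns (retained object, :class:`DedupReport`).
    """
    if isinstance(obj, ReadPairSet):
        w = min(window, obj.read_length)
        keys = np.concatenate([obj.seq1[:, :w], obj.seq2[:, :w]], axis=1)
        mask = _first_occurrence_mask(_void_view(keys))
        retained = ReadPairSet(
            obj.seq1[mask], obj.seq2[mask], obj.source[mask], obj.sources, obj.read_length
        )
        return retained, DedupReport("sequence", len(obj), int(mask.sum()))
    frags: FragmentSet = obj
    keys = np.concatenate([frags.key1, frags.key2], axis=1)
    mask = _first_occurrence_mask(_void_view(keys))
    return frags.subset(mask), DedupReport("sequence", len(frags), int(mask.sum()))


def dedup_by_position(frags: FragmentSet):
    """Keep one fragment per (contig, start, end); first in input order wins."""
    keys = np.stack(
        [frags.contig_index.astype(np.int64), frags.start, frags.end], axis=1
    )
    mask = _first_occurrence_mask(_void_view(keys))
    return frags.subset(mask), DedupReport("position", len(frags), int(mask.sum()))


# ---------------------------------------------------------------------------
# SAM interchange


def write_sam(frags: FragmentSet, reads: ReadPairSet, reference: Reference, path) -> None:
    """Write mapped proper pairs as minimal SAM records."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c.name, "LN": len(c.sequence)} for c in reference.contigs],
    }
    L = reads.read_length
    name_to_tid = {sq["SN"]: i for i, sq in enumerate(header["SQ"])}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i in range(len(frags)):
            ri = frags.read_index[i]
            contig = frags.contig_names[frags.contig_index[i]]
            tid = name_to_tid[contig]
            start, end = int(frags.start[i]), int(frags.end[i])
            tlen = end - start
            m1f = bool(frags.m1_forward[i])
            for mate in (1, 2):
                a = pysam.AlignedSegment()
                a.query_name = f"sim:{ri:07d}"
                fwd = m1f if mate == 1 else not m1f
                a.flag = (
                    0x1
                    | 0x2
                    | (0x10 if not fwd else 0)
                    | (0x20 if fwd else 0)
                    | (0x40 if mate == 1 else 0x80)
                )
                a.reference_id = tid
                a.reference_start = start if fwd else end - L
                a.next_reference_id = tid
                a.next_reference_start = end - L if fwd else start
                a.template_length = tlen if fwd else -tlen
                a.cigarstring = f"{L}M"
                seq = decode_sequence((reads.seq1 if mate == 1 else reads.seq2)[ri])
                if not fwd:
                    from .genome import reverse_complement

                    seq = reverse_complement(seq)
                a.query_sequence = seq
                a.query_qualities = pysam.qualitystring_to_array("I" * L)
                out.write(a)


def read_sam(path, max_insert: int = 2000, dedup_window: int = 50) -> FragmentSet:
    """Ingest externally produced SAM and apply the proper-pair filters.

    Keeps a pair iff both primary mates are mapped to the same contig in
    convergent orientation with outer span <= ``max_insert``. Dedup keys are
    rebuilt from the original read orientation.
    """
    from .genome import encode_sequence, reverse_complement

    pending: dict[str, pysam.AlignedSegment] = {}
    rows = []
    try:
        fh = pysam.AlignmentFile(str(path), "r", check_sq=False)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    with fh:
        contig_names = list(fh.references)
        for aln in fh:
            if aln.is_secondary or aln.is_supplementary:
                continue
            other = pending.pop(aln.query_name, None)
            if other is None:
                pending[aln.query_name] = aln
                continue
            r1, r2 = (aln, other) if aln.is_read1 else (other, aln)
            if r1.is_unmapped or r2.is_unmapped:
                continue
            if r1.reference_id != r2.reference_id:
                continue
            if r1.is_reverse == r2.is_reverse:
                continue
            fwd, rev = (r1, r2) if not r1.is_reverse else (r2, r1)
            start = fwd.reference_start
            end = rev.reference_end
            if end is None or start > rev.reference_start or end - start > max_insert:
                continue
            seqs = []
            for r in (r1, r2):
                s = r.query_sequence or ""
                if r.is_reverse:
                    s = reverse_complement(s)
                seqs.append(s)
            rows.append(
                (r1.reference_id, start, end, not r1.is_reverse, seqs[0], seqs[1])
            )
    n = len(rows)
    w = dedup_window
    key1 = np.full((n, w), 4, dtype=np.uint8)
    key2 = np.full((n, w), 4, dtype=np.uint8)
    contig_index = np.empty(n, dtype=np.int32)
    start = np.empty(n, dtype=np.int64)
    end = np.empty(n, dtype=np.int64)
    m1f = np.empty(n, dtype=bool)
    for i, (tid, s, e, fwd, s1, s2) in enumerate(rows):
        contig_index[i] = tid
        start[i], end[i], m1f[i] = s, e, fwd
        for key, seq in ((key1, s1), (key2, s2)):
            c = encode_sequence(seq[:w])
            key[i, : len(c)] = c
    return FragmentSet(
        contig_names=contig_names,
        contig_index=contig_index,
        start=start,
        end=end,
        multi_unit=np.zeros(n, dtype=bool),
        m1_forward=m1f,
        key1=key1,
        key2=key2,
        read_index=np.arange(n, dtype=np.int64),
        stats=MappingStats(n_pairs=n, n_mapped=n),
    )
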