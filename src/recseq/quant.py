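"""Bin-level quantification and normalization.

Deduplicated proper-pair fragments are counted into fixed-width bins tiling
every contig from coordinate 0 (partial terminal bins kept); a fragment
contributes 1 to every bin its outer span overlaps. Fragments overlapping an
excluded feature (rDNA-like, the 2-micron episome, the ubiquitin-ligase-like
locus cleaved by the mother-enrichment system) are dropped entirely, and
bins wholly inside exclusions are omitted from output.

Within-library values are fragments-per-million-included. Across samples,
REC-seq libraries prepared with a panel that spares the 2-micron episome are
put on a common scale with the anchored scaling factor

    SF_1 = ((2u fragments in total DNA) / (nonrepetitive chromosomal
            fragments in total DNA)) / (2u fragments in REC-seq)
    SF   = SF_1 / SF_1(control)

so the control sample has SF == 1 exactly and other samples get a minimal
linear correction that preserves between-sample 2-micron differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AnchorMissingError, InputError, NormalizationError
from .genome import REPEAT_LABELS, FeatureAnnotation, Reference
from .readproc import FragmentSet

DEFAULT_EXCLUDE_LABELS = ("rDNA_like", "two_micron", "UBC9_like")

#: tie-break priority when a bin overlaps several feature labels equally
CLASSIFY_PRIORITY = (
    "tandem_array",
    "rDNA_like",
    "two_micron",
    "UBC9_like",
    "Ty_like",
    "subtelomere",
    "unique",
)


@dataclass(frozen=True)
class ExclusionSet:
    """Features whose fragments are excluded from quantification."""

    features: tuple[FeatureAnnotation, ...]

    @classmethod
    def from_reference(
        cls, reference: Reference, labels: Sequence[str] = DEFAULT_EXCLUDE_LABELS
    ) -> "ExclusionSet":
        return cls(tuple(f for f in reference.features if f.label in labels))

    def intervals_by_contig(self) -> dict[str, np.ndarray]:
        out: dict[str, list[tuple[int, int]]] = {}
        for f in self.features:
            out.setdefault(f.contig, []).append((f.start, f.end))
        return {c: _merge_intervals(iv) for c, iv in out.items()}


def _merge_intervals(ivs: Iterable[tuple[int, int]]) -> np.ndarray:
    ivs = sorted(ivs)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64).reshape(-1, 2)


def fragments_overlap_intervals(
    frags: FragmentSet, intervals_by_contig: Mapping[str, np.ndarray]
) -> np.ndarray:
    """Boolean mask: fragment overlaps any interval on its contig."""
    mask = np.zeros(len(frags), dtype=bool)
    for ci, name in enumerate(frags.contig_names):
        ivs = intervals_by_contig.get(name)
        if ivs is None or len(ivs) == 0:
            continue
        on = frags.contig_index == ci
        if not on.any():
            continue
        s, e = frags.start[on], frags.end[on]
        j = np.searchsorted(ivs[:, 0], e, side="left") - 1
        hit = (j >= 0) & (ivs[np.clip(j, 0, None), 1] > s)
        mask[np.nonzero(on)[0]] = hit
    return mask


@dataclass
class BinCounts:
    """Per-bin fragment counts for one library on one bin grid."""

    library_id: str
    bin_size: int
    contig_names: list[str]
    contig_lengths: list[int]
    counts: dict[str, np.ndarray]
    included: dict[str, np.ndarray]  # False where the bin lies wholly in an exclusion
    total_included: int  # number of included fragments

    def n_bins(self) -> int:
        return sum(len(c) for c in self.counts.values())

    def flat_counts(self) -> np.ndarray:
        return np.concatenate([self.counts[c] for c in self.contig_names])

    def flat_included(self) -> np.ndarray:
        return np.concatenate([self.included[c] for c in self.contig_names])

    def bin_table(self) -> pd.DataFrame:
        rows = []
        for name, length in zip(self.contig_names, self.contig_lengths):
            nb = len(self.counts[name])
            starts = np.arange(nb, dtype=np.int64) * self.bin_size
            ends = np.minimum(starts + self.bin_size, length)
            rows.append(
                pd.DataFrame(
                    {
                        "contig": name,
                        "start": starts,
                        "end": ends,
                        "count": self.counts[name],
                        "included": self.included[name],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def bin_counts(
    frags: FragmentSet,
    reference: Reference,
    bin_size: int,
    exclusions: ExclusionSet | None = None,
    library_id: str = "",
) -> BinCounts:
    """Count deduplicated fragments into ``bin_size`` bins with exclusions."""
    if bin_size < 1:
        raise InputError("bin size must be >= 1")
    contig_names = reference.contig_names()
    contig_lengths = [len(c.sequence) for c in reference.contigs]
    excl_ivs = exclusions.intervals_by_contig() if exclusions else {}
    drop = fragments_overlap_intervals(frags, excl_ivs) if excl_ivs else np.zeros(
        len(frags), dtype=bool
    )
    keep = ~drop
    counts: dict[str, np.ndarray] = {}
    included: dict[str, np.ndarray] = {}
    name_to_i = {n: i for i, n in enumerate(contig_names)}
    for name, length in zip(contig_names, contig_lengths):
        nb = (length + bin_size - 1) // bin_size
        on = keep & (frags.contig_index == name_to_i[name])
        d = np.zeros(nb + 1, dtype=np.int64)
        if on.any():
            first = frags.start[on] // bin_size
            last = (frags.end[on] - 1) // bin_size
            np.add.at(d, first, 1)
            np.add.at(d, np.minimum(last + 1, nb), -1)
        counts[name] = np.cumsum(d[:-1])
        inc = np.ones(nb, dtype=bool)
        for s, e in excl_ivs.get(name, ()):
            # bin [b*k, (b+1)*k) lies wholly inside [s, e) iff b*k >= s and (b+1)*k <= e
            b0 = int(-(-s // bin_size))
            b1 = int(e // bin_size)
            inc[b0:b1] = False
        included[name] = inc
    return BinCounts(
        library_id=library_id,
        bin_size=bin_size,
        contig_names=contig_names,
        contig_lengths=contig_lengths,
        counts=counts,
        included=included,
        total_included=int(keep.sum()),
    )


def normalize_total(bins: BinCounts) -> dict[str, np.ndarray]:
    """Per-bin values in fragments-per-million-included."""
    if bins.total_included <= 0:
        raise NormalizationError("library has zero included fragments")
    scale = 1e6 / bins.total_included
    return {c: bins.counts[c] * scale for c in bins.contig_names}


@dataclass(frozen=True)
class NormalizationFactors:
    sf1: float
    sf1_control: float

    def __post_init__(self):
        if self.sf1 <= 0 or self.sf1_control <= 0:
            raise NormalizationError("scaling factors must be strictly positive")

    @property
    def sf(self) -> float:
        return self.sf1 / self.sf1_control


def compute_scaling_factors(
    recseq_two_micron: int,
    total_two_micron: int,
    total_nonrepetitive: int,
    sf1_control: float | None = None,
) -> NormalizationFactors:
    """Anchored scaling factors; ``sf1_control=None`` marks the sample as control.

    Requires a REC-seq library prepared with a panel sparing the 2-micron
    episome (otherwise its count is zero and no anchor exists).
    """
    if recseq_two_micron <= 0:
        raise AnchorMissingError(
            "no 2-micron fragments in the REC-seq library; "
            "was the library prepared with an episome-sparing panel?"
        )
    if total_two_micron <= 0 or total_nonrepetitive <= 0:
        raise NormalizationError("total-DNA anchor counts must be positive")
    sf1 = (total_two_micron / total_nonrepetitive) / recseq_two_micron
    if sf1_control is None:
        sf1_control = sf1  # control sample: SF == 1 exactly
    return NormalizationFactors(sf1=sf1, sf1_control=sf1_control)


def apply_scaling(
    values: Mapping[str, np.ndarray], factors: NormalizationFactors
) -> dict[str, np.ndarray]:
    return {c: v * factors.sf for c, v in values.items()}


def count_feature_fragments(frags: FragmentSet, features: Iterable[FeatureAnnotation]) -> int:
    """Number of fragments overlapping any of the given features."""
    ivs: dict[str, list[tuple[int, int]]] = {}
    for f in features:
        ivs.setdefault(f.contig, []).append((f.start, f.end))
    merged = {c: _merge_intervals(v) for c, v in ivs.items()}
    return int(fragments_overlap_intervals(frags, merged).sum())


def count_nonrepetitive_fragments(frags: FragmentSet, reference: Reference) -> int:
    """Fragments not overlapping any annotated repeat feature."""
    rep = [f for f in reference.features if f.label in REPEAT_LABELS]
    ivs: dict[str, list[tuple[int, int]]] = {}
    for f in rep:
        ivs.setdefault(f.contig, []).append((f.start, f.end))
    merged = {c: _merge_intervals(v) for c, v in ivs.items()}
    return int((~fragments_overlap_intervals(frags, merged)).sum())


def classify_bins(bins: BinCounts, reference: Reference) -> dict[str, np.ndarray]:
    """Per-bin feature label by maximal overlap; ties broken by priority."""
    prio = {label: i for i, label in enumerate(CLASSIFY_PRIORITY)}
    out: dict[str, np.ndarray] = {}
    for name, length in zip(bins.contig_names, bins.contig_lengths):
        nb = len(bins.counts[name])
        best_ov = np.zeros(nb, dtype=np.int64)
        best_pr = np.full(nb, prio["unique"], dtype=np.int64)
        labels = np.full(nb, "unique", dtype=object)
        starts = np.arange(nb, dtype=np.int64) * bins.bin_size
        ends = np.minimum(starts + bins.bin_size, length)
        for f in reference.features:
            if f.contig != name:
                continue
            ov = np.minimum(ends, f.end) - np.maximum(starts, f.start)
            ov = np.maximum(ov, 0)
            p = prio.get(f.label, prio["unique"])
            better = (ov > best_ov) | ((ov == best_ov) & (ov > 0) & (p < best_pr))
            labels[better] = f.label
            best_pr[better] = p
            best_ov[better] = ov[better]
        out[name] = labels
    return out


def region_bin_slice(
    bins: BinCounts, region: FeatureAnnotation | tuple[str, int, int]
) -> tuple[str, slice]:
    if isinstance(region, FeatureAnnotation):
        contig, start, end = region.contig, region.start, region.end
    else:
        contig, start, end = region
    if contig not in bins.counts:
        raise InputError(f"unknown contig {contig!r}")
    lo = start // bins.bin_size
    hi = -(-end // bins.bin_size)
    if hi <= lo:
        raise InputError("empty region")
    return contig, slice(lo, hi)


def fold_enrichment(
    values_a: Mapping[str, np.ndarray],
    values_b: Mapping[str, np.ndarray],
    bins: BinCounts,
    region: FeatureAnnotation | tuple[str, int, int],
    pseudocount: float = 0.5,
) -> float:
    """Ratio of mean per-bin values over a region, with a pseudocount per bin."""
    contig, sl = region_bin_slice(bins, region)
    a = np.asarray(values_a[contig][sl], dtype=float)
    b = np.asarray(values_b[contig][sl], dtype=float)
    if a.size == 0:
        raise InputError("empty region")
    return float((a + pseudocount).mean() / (b + pseudocount).mean())


# ---------------------------------------------------------------------------
# Exports


def write_bedgraph(values: Mapping[str, np.ndarray], bins: BinCounts, path) -> None:
    with open(path, "w") as fh:
        for name, length in zip(bins.contig_names, bins.contig_lengths):
            vals = values[name]
            inc = bins.included[name]
            for i in range(len(vals)):
                if not inc[i]:
                    continue
                s = i * bins.bin_size
                e = min(s + bins.bin_size, length)
                fh.write(f"{name}\t{s}\t{e}\t{vals[i]:.6g}\n")


def bins_to_wide_table(all_bins: Sequence[BinCounts]) -> pd.DataFrame:
    """Bin x library count matrix over included bins shared by all libraries."""
    base = all_bins[0].bin_table()[["contig", "start", "end", "included"]]
    out = base.copy()
    for b in all_bins:
        t = b.bin_table()
        if not (t["contig"].equals(base["contig"]) and t["start"].equals(base["start"])):
            raise InputError("libraries quantified on different bin grids")
        out[b.library_id] = t["count"]
        out["included"] &= t["included"]
    return out[out["included"]].drop(columns="included").reset_index(drop=True)


def write_scatter_table(
    bins: BinCounts,
    labels: Mapping[str, np.ndarray],
    values_a: Mapping[str, np.ndarray],
    values_b: Mapping[str, np.ndarray],
    path,
    names: tuple[str, str] = ("valueA", "valueB"),
) -> None:
    """Per-bin comparison table (linear values plus log2 columns)."""
    with open(path, "w") as fh:
        fh.write(
            "contig\tstart\tend\tlabel\t"
            f"{names[0]}\t{names[1]}\tlog2_{names[0]}\tlog2_{names[1]}\n"
        )
        for name, length in zip(bins.contig_names, bins.contig_lengths):
            va, vb = values_a[name], values_b[name]
            lab = labels[name]
            inc = bins.included[name]
            for i in range(len(va)):
                if not inc[i]:
                    continue
                s = i * bins.bin_size
                e = min(s + bins.bin_size, length)
                la = np.log2(va[i] + 0.5)
                lb = np.log2(vb[i] + 0.5)
                fh.write(
                    f"{name}\t{s}\t{e}\t{lab[i]}\t{va[i]:.6g}\t{vb[i]:.6g}"
                    f"\t{la:.4f}\t{lb:.4f}\n"
                )
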