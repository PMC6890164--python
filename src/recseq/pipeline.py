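"""End-to-end orchestration: simulate, sequence, map, quantify, test.

One master seed drives everything; per-stage seeds are derived with a
documented counter scheme (``SeedSequence((master, stage_index, ...))``) so
stages can be rerun independently yet reproducibly. The run configuration is
a strict YAML document: unknown keys are errors.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import ageing, diff, libsim, quant, readproc
from .errors import ConfigError, InputError
from .genome import Reference, build_reference, default_genome_spec, write_bed, write_fasta
from .libsim import CircularSpecies, ReadPairSet, excise_species, panel_from_names

STAGES = ("genome", "ageing", "library", "mapping", "quant", "diff", "report")


def stage_seed(master: int, stage: str, *extra: int) -> int:
    """Derive a per-stage (optionally per-library) seed below 2^31."""
    if stage not in STAGES:
        raise ConfigError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence((int(master), STAGES.index(stage), *map(int, extra)))
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class AgeingConfig:
    n_divisions: int = 24
    replicate_cv: float = 0.1  # between-replicate biological variability
    presets: dict = field(
        default_factory=lambda: {
            "tandem_array": {"plus_cu": "cup1_wt_plus_cu", "minus_cu": "cup1_wt_minus_cu"},
            "rDNA_like": {"plus_cu": "erc_wt", "minus_cu": "erc_wt"},
            "subtelomere": {"plus_cu": "subtelomere_wt", "minus_cu": "subtelomere_wt"},
            "Ty_like": {"plus_cu": "ty_wt", "minus_cu": "ty_wt"},
        }
    )
    two_micron_abundance: float = 20.0
    ubc9_circle_abundance: float = 2.0
    cup1_unit_fractions: tuple = (0.5, 0.3, 0.2)  # 1-, 2-, 3-unit circles


@dataclass
class LibraryConfig:
    panel: tuple = ("EagI", "PvuI", "PvuII")
    rounds: int = 2
    p_cut: float = 1.0
    leak_fraction: float = 0.001
    depth_recseq: int = 200_000
    depth_total: int = 50_000
    make_total: bool = False
    make_exo_only: bool = True
    read_length: int = 75
    insert_mean: float = 300.0
    insert_sd: float = 60.0
    insert_min: int = 100
    insert_max: int = 700
    error_rate: float = 0.001


@dataclass
class AnalysisConfig:
    bin_profile: int = 20
    bin_stats: int = 100
    dedup_window: int = 50
    max_insert: int = 2000
    mismatches: int = 2
    alpha: float = 0.05
    correction: str = "none"


@dataclass
class RunConfig:
    seed: int = 0
    replicates: int = 3
    conditions: tuple = ("plus_cu", "minus_cu")
    control_condition: str = "minus_cu"
    ageing: AgeingConfig = field(default_factory=AgeingConfig)
    library: LibraryConfig = field(default_factory=LibraryConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_tuples_to_lists(self.to_dict()), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        return _dataclass_from_dict(cls, data, "config")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_tuples_to_lists(v) for v in obj]
    return obj


def _dataclass_from_dict(cls, data: Mapping, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"unknown key(s) under {path}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        if name in ("ageing",) and isinstance(value, Mapping):
            kwargs[name] = _dataclass_from_dict(AgeingConfig, value, f"{path}.{name}")
        elif name in ("library",) and isinstance(value, Mapping):
            kwargs[name] = _dataclass_from_dict(LibraryConfig, value, f"{path}.{name}")
        elif name in ("analysis",) and isinstance(value, Mapping):
            kwargs[name] = _dataclass_from_dict(AnalysisConfig, value, f"{path}.{name}")
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


# ---------------------------------------------------------------------------
# Simulation assembly


def build_species_for_replicate(
    reference: Reference,
    cfg: RunConfig,
    condition: str,
    replicate: int,
) -> list[CircularSpecies]:
    """Circle species and abundances for one biological replicate.

    Mean abundances come from the per-division dynamics model evaluated at
    the configured age; replicate-to-replicate biological variability is a
    gamma multiplier with coefficient of variation ``replicate_cv``.
    """
    acfg = cfg.ageing
    ci = cfg.conditions.index(condition)
    rng = np.random.default_rng(stage_seed(cfg.seed, "ageing", ci, replicate))
    cv = acfg.replicate_cv

    def jitter(mean: float) -> float:
        if cv <= 0 or mean <= 0:
            return mean
        shape = 1.0 / cv**2
        return float(mean * rng.gamma(shape, 1.0 / shape))

    species: list[CircularSpecies] = []
    for feat in reference.features:
        if feat.label == "two_micron":
            species.append(
                dataclasses.replace(
                    excise_species(reference, feat, 1),
                    abundance=jitter(acfg.two_micron_abundance),
                )
            )
            continue
        if feat.label == "UBC9_like":
            species.append(
                dataclasses.replace(
                    excise_species(reference, feat, 1),
                    abundance=jitter(acfg.ubc9_circle_abundance),
                )
            )
            continue
        preset_map = acfg.presets.get(feat.label)
        if preset_map is None:
            continue
        preset = preset_map[condition] if isinstance(preset_map, Mapping) else preset_map
        params = ageing.preset_params(preset, n_divisions=acfg.n_divisions)
        mean = ageing.expected_copies(params, acfg.n_divisions)
        if feat.label == "tandem_array":
            for n_units, frac in enumerate(acfg.cup1_unit_fractions, start=1):
                copies = len(feat) // (feat.unit_length or len(feat))
                if n_units > copies:
                    continue
                species.append(
                    dataclasses.replace(
                        excise_species(reference, feat, n_units),
                        abundance=jitter(mean * frac),
                    )
                )
        else:
            species.append(
                dataclasses.replace(
                    excise_species(reference, feat, 1), abundance=jitter(mean)
                )
            )
    return species


def make_reads(
    reference: Reference,
    species: Sequence[CircularSpecies],
    mode: str,
    cfg: RunConfig,
    seed: int,
    depth: int | None = None,
) -> ReadPairSet:
    lcfg = cfg.library
    panel = panel_from_names(lcfg.panel, reference.enzyme_motifs)
    pool = libsim.build_library_pool(
        reference,
        species,
        mode,
        panel=panel,
        rounds=lcfg.rounds,
        p_cut=lcfg.p_cut,
        leak_fraction=lcfg.leak_fraction,
        seed=seed,
    )
    if depth is None:
        depth = lcfg.depth_recseq if mode == "recseq" else lcfg.depth_total
    return libsim.generate_reads(
        pool,
        depth,
        read_length=lcfg.read_length,
        insert_mean=lcfg.insert_mean,
        insert_sd=lcfg.insert_sd,
        insert_min=lcfg.insert_min,
        insert_max=lcfg.insert_max,
        error_rate=lcfg.error_rate,
        seed=seed + 1,
    )


@dataclass
class LibraryAnalysis:
    library_id: str
    reads: ReadPairSet
    frags: readproc.FragmentSet
    dedup_reports: list
    bins_profile: quant.BinCounts
    bins_stats: quant.BinCounts


def analyze_reads(
    reads: ReadPairSet,
    reference: Reference,
    cfg: RunConfig,
    library_id: str,
    index: readproc.GenomeIndex | None = None,
    exclusions: quant.ExclusionSet | None = None,
) -> LibraryAnalysis:
    an = cfg.analysis
    frags = readproc.map_reads(
        reads,
        reference,
        max_insert=an.max_insert,
        max_mismatches=an.mismatches,
        dedup_window=an.dedup_window,
        index=index,
    )
    frags, rep_seq = readproc.dedup_by_sequence(frags, window=an.dedup_window)
    frags, rep_pos = readproc.dedup_by_position(frags)
    if exclusions is None:
        exclusions = quant.ExclusionSet.from_reference(reference)
    b20 = quant.bin_counts(frags, reference, an.bin_profile, exclusions, library_id)
    b100 = quant.bin_counts(frags, reference, an.bin_stats, exclusions, library_id)
    return LibraryAnalysis(library_id, reads, frags, [rep_seq, rep_pos], b20, b100)


NUISANCE_PREFIXES = ("rDNA_like:", "two_micron:")


def nuisance_read_fraction(reads: ReadPairSet) -> float:
    """Fraction of truth-tagged reads from rDNA-like circles or the episome."""
    labels = reads.source_labels()
    nuis = np.zeros(len(reads), dtype=bool)
    for p in NUISANCE_PREFIXES:
        nuis |= np.char.startswith(labels.astype(str), p)
    return float(nuis.mean()) if len(reads) else 0.0


def condition_mean_values(libraries: dict, condition: str, grid: str = "profile"):
    """Replicate-averaged fragments-per-million for one condition's REC-seq libs."""
    vals = None
    n = 0
    for (cond, rep, mode), la in libraries.items():
        if cond != condition or mode != "recseq":
            continue
        bins = la.bins_profile if grid == "profile" else la.bins_stats
        v = quant.normalize_total(bins)
        if vals is None:
            vals = {c: arr.astype(float).copy() for c, arr in v.items()}
        else:
            for c in vals:
                vals[c] += v[c]
        n += 1
    if vals is None:
        raise InputError(f"no REC-seq libraries for condition {condition!r}")
    return {c: arr / n for c, arr in vals.items()}


@dataclass
class RunResult:
    config: RunConfig
    reference: Reference
    cohort: pd.DataFrame
    libraries: dict  # (condition, replicate, mode) -> LibraryAnalysis
    count_matrix: diff.CountMatrix | None
    differential: pd.DataFrame | None
    fold_cup1: float | None
    nuisance_fractions: dict
    scaling: dict  # sample -> NormalizationFactors (2u-sparing panels only)

    def condition_mean_values(self, condition: str, grid: str = "profile"):
        return condition_mean_values(self.libraries, condition, grid)


def run_experiment(cfg: RunConfig, reference: Reference | None = None) -> RunResult:
    """Simulate and analyze the full experiment in memory."""
    if reference is None:
        reference = build_reference(default_genome_spec(stage_seed(cfg.seed, "genome")))
    index = readproc.GenomeIndex(reference)
    exclusions = quant.ExclusionSet.from_reference(reference)
    cohort_keys = {}
    for label, m in cfg.ageing.presets.items():
        for cond in cfg.conditions:
            preset = m[cond] if isinstance(m, Mapping) else m
            cohort_keys[(label, cond)] = preset
    cohort = ageing.simulate_cohort(
        cohort_keys, n_mothers=200, seed=stage_seed(cfg.seed, "ageing")
    )
    libraries: dict = {}
    nuisance = {}
    for cond in cfg.conditions:
        ci = cfg.conditions.index(cond)
        for rep in range(cfg.replicates):
            species = build_species_for_replicate(reference, cfg, cond, rep)
            modes = ["recseq"]
            if cfg.library.make_total:
                modes.append("total")
            if cfg.library.make_exo_only and rep == 0:
                modes.append("exo_only")
            for mode in modes:
                seed = stage_seed(cfg.seed, "library", ci, rep, modes.index(mode))
                reads = make_reads(reference, species, mode, cfg, seed)
                lid = f"{cond}_rep{rep}_{mode}"
                libraries[(cond, rep, mode)] = analyze_reads(
                    reads, reference, cfg, lid, index, exclusions
                )
                nuisance[lid] = nuisance_read_fraction(reads)
    # differential on the statistics grid, REC-seq libraries only
    # order libraries test-condition first so log2 fold changes read test/control
    order = lambda key: (key[0] == cfg.control_condition, key[0], key[1])
    recs = [
        la
        for (c, r, m), la in sorted(libraries.items(), key=lambda kv: order(kv[0]))
        if m == "recseq"
    ]
    groups = [c for (c, r, m) in sorted(libraries, key=order) if m == "recseq"]
    cm = differential = None
    enough_reps = any(groups.count(g) >= 2 for g in set(groups))
    if len(set(groups)) == 2 and enough_reps:
        wide = quant.bins_to_wide_table([la.bins_stats for la in recs])
        labels_by_contig = quant.classify_bins(recs[0].bins_stats, reference)
        lab = [
            labels_by_contig[c][s // recs[0].bins_stats.bin_size]
            for c, s in zip(wide["contig"], wide["start"])
        ]
        meta = wide[["contig", "start", "end"]].copy()
        meta["label"] = lab
        cm = diff.CountMatrix(
            counts=wide[[la.library_id for la in recs]].to_numpy(),
            groups=groups,
            library_ids=[la.library_id for la in recs],
            bin_meta=meta,
        )
        differential = diff.run_differential(
            cm, alpha=cfg.analysis.alpha, correction=cfg.analysis.correction
        )
    # copper-array fold enrichment between the two conditions (profile grid)
    fold = None
    arrays = reference.features_by_label("tandem_array")
    if arrays and len(cfg.conditions) == 2 and recs:
        test_cond = next(c for c in cfg.conditions if c != cfg.control_condition)
        fold = quant.fold_enrichment(
            condition_mean_values(libraries, test_cond),
            condition_mean_values(libraries, cfg.control_condition),
            recs[0].bins_profile,
            arrays[0],
        )
    # anchored scaling factors (only meaningful if the panel spares the episome)
    scaling = {}
    if cfg.library.make_total:
        scaling = compute_all_scaling(cfg, reference, libraries)
    return RunResult(
        cfg, reference, cohort, libraries, cm, differential, fold, nuisance, scaling
    )


def compute_all_scaling(cfg: RunConfig, reference: Reference, libraries: dict) -> dict:
    two_mu = [f for f in reference.features if f.label == "two_micron"]
    control = cfg.control_condition
    factors: dict = {}
    control_sf1 = None
    ordered = sorted({(c, r) for (c, r, m) in libraries}, key=lambda x: (x[0] != control, x))
    for cond, rep in ordered:
        la_rec = libraries.get((cond, rep, "recseq"))
        la_tot = libraries.get((cond, rep, "total"))
        if la_rec is None or la_tot is None:
            continue
        rec_2u = quant.count_feature_fragments(la_rec.frags, two_mu)
        tot_2u = quant.count_feature_fragments(la_tot.frags, two_mu)
        tot_nonrep = quant.count_nonrepetitive_fragments(la_tot.frags, reference)
        try:
            nf = quant.compute_scaling_factors(
                rec_2u, tot_2u, tot_nonrep, sf1_control=control_sf1
            )
        except Exception:
            continue
        if cond == control and control_sf1 is None:
            control_sf1 = nf.sf1
        factors[f"{cond}_rep{rep}"] = nf
    return factors


# ---------------------------------------------------------------------------
# Artifacts


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig, outdir, stages: Sequence[str] | None = None) -> Path:
    """Run the pipeline and write artifacts + a checksum manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    result = run_experiment(cfg)
    ref = result.reference
    write_fasta(ref.contigs, outdir / "reference.fasta")
    write_bed(ref.features, outdir / "features.bed")
    cfg.to_yaml(outdir / "config.yaml")
    ageing.write_cohort_tsv(result.cohort, outdir / "cohort.tsv")
    dedup_rows = []
    for (cond, rep, mode), la in sorted(result.libraries.items(), key=lambda kv: str(kv[0])):
        stem = outdir / la.library_id
        la.reads.to_fastq(f"{stem}_R1.fastq.gz", f"{stem}_R2.fastq.gz", prefix=la.library_id)
        readproc.write_sam(la.frags, la.reads, ref, f"{stem}.sam")
        vals = quant.normalize_total(la.bins_profile)
        quant.write_bedgraph(vals, la.bins_profile, f"{stem}.bedgraph")
        for r in la.dedup_reports:
            dedup_rows.append((la.library_id, r.pass_name, r.n_input, r.n_retained))
    pd.DataFrame(
        dedup_rows, columns=["library", "pass", "n_input", "n_retained"]
    ).to_csv(outdir / "dedup_report.tsv", sep="\t", index=False)
    if result.differential is not None:
        diff.write_differential_tsv(result.differential, outdir / "differential.tsv")
    if result.scaling:
        with open(outdir / "scaling_factors.tsv", "w") as fh:
            fh.write("sample\tSF1\tSF\n")
            for sample, nf in result.scaling.items():
                fh.write(f"{sample}\t{nf.sf1:.6g}\t{nf.sf:.6g}\n")
    summary = summarize(result)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    manifest = {
        "seed": cfg.seed,
        "elapsed_s": round(time.time() - t0, 2),
        "artifacts": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir


def summarize(result: RunResult) -> dict:
    """Headline numbers of a run (also used by the report command)."""
    cfg = result.config
    sig = None
    top_labels = None
    if result.differential is not None:
        d = result.differential
        sig = int(d["significant"].sum())
        top = d[d["significant"]].head(20)
        top_labels = top["label"].tolist() if "label" in top else None
    return {
        "conditions": list(cfg.conditions),
        "replicates": cfg.replicates,
        "cup1_fold_enrichment": result.fold_cup1,
        "nuisance_read_fraction": result.nuisance_fractions,
        "n_significant_bins": sig,
        "top_significant_bin_labels": top_labels,
        "scaling_factors": {k: {"SF1": v.sf1, "SF": v.sf} for k, v in result.scaling.items()},
    }


def report(run_dir) -> str:
    """Human-readable summary composed from run artifacts."""
    run_dir = Path(run_dir)
    spath = run_dir / "summary.json"
    if not spath.exists():
        raise InputError(f"missing artifact: {spath}")
    with open(spath) as fh:
        s = json.load(fh)
    lines = [
        "REC-seq simulation run summary",
        f"  conditions: {', '.join(s['conditions'])} ({s['replicates']} replicates)",
    ]
    if s.get("cup1_fold_enrichment") is not None:
        lines.append(
            f"  copper-array fold enrichment (test vs control): "
            f"{s['cup1_fold_enrichment']:.2f}"
        )
    for lib, frac in sorted(s.get("nuisance_read_fraction", {}).items()):
        lines.append(f"  nuisance (rDNA-like + episome) read fraction, {lib}: {frac:.4f}")
    if s.get("n_significant_bins") is not None:
        lines.append(f"  significant bins: {s['n_significant_bins']}")
        if s.get("top_significant_bin_labels"):
            lines.append(
                "  top significant bin labels: "
                + ", ".join(s["top_significant_bin_labels"][:10])
            )
    for sample, nf in s.get("scaling_factors", {}).items():
        lines.append(f"  scaling {sample}: SF1={nf['SF1']:.3g} SF={nf['SF']:.3g}")
    return "\n".join(lines)
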