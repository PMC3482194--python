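"""End-to-end orchestration: simulate -> resolve -> classify -> repeats ->
APA -> strata, with a machine-readable report keyed by figure analogs.

The report tables mirror the analysis panels: mapping uniqueness (fig1b),
region proportions with Fisher tests against the exon control (fig1c),
replicate mean RUD with a Welch t test (fig2), length/exon stratification
with K-S tests (fig3a), per-gene read-through folds (fig3d), repeat-class
fold changes in four read categories (fig4a-fig4d), full-length LINE-1
proportions (fig4e) and the LINE-1 3'-end bin profile with its chi-squared
comparison (fig4f). Rerunning with the same configuration and seed yields
byte-identical tables.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import shutil
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import (
    STATUS_NON_UNIQUE,
    STATUS_UNIQUE,
    STATUS_UNMAPPED,
    parse_psl_lines,
    resolve_all,
)
from .annotate import (
    GeneIndex,
    classify_read,
    compare_region_tables,
    tabulate_regions,
)
from .apa import (
    CoverageTrack,
    gene_rud,
    normalize_readthrough,
    readthrough_index,
    sample_background,
    sample_rud,
)
from .model import REPEAT_CLASSES, ConditionParams
from .repeats import (
    attribute_repeats,
    attribute_unmapped,
    compare_end_profiles,
    line1_end_profile,
    line1_full_length_filter,
    repeat_fold_change,
)
from .simulate import (
    ExpressionSimConfig,
    GenomeConfig,
    build_toy_genome,
    emit_truth_psl,
    simulate_expression,
    simulate_reads,
)
from .stats import fisher_exact_2x2, proportion_sd, welch_t_test
from .strata import cdf_compare, expression_changes, stratify_genes


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class ConfigError(ValueError):
    pass


_CONDITION_KEYS = {
    "readthrough_prob", "extension_scale", "distal_frac", "line1_rate",
    "sine_rate", "ltr_rate", "intergenic_rate", "junk_rate",
    "line1_consensus_frac", "unspliced_frac", "error_rate", "n_reads",
}

_TOP_KEYS = {
    "seed", "conditions", "reference_condition", "genome", "expression",
    "n_replicates", "replicate_reads", "gap_threshold", "utr3_ext",
    "utr5_ext", "line1_min_length", "n_bins", "short_quantile",
    "pseudo_signal", "readthrough_up_window", "readthrough_down_window",
    "readthrough_down_offset", "background_window",
}


@dataclass
class PipelineConfig:
    """Validated pipeline settings; defaults hold the analysis constants
    (score gap 10, 4 kb / 1 kb extension windows, >= 6 kb LINE-1, 5 bins,
    lowest-20% length cutoff)."""

    seed: int = 1
    conditions: Dict[str, dict] = field(default_factory=lambda: {
        "WT": {"readthrough_prob": 0.1, "distal_frac": 0.3,
               "line1_rate": 0.02, "n_reads": 12000},
        "KO": {"readthrough_prob": 0.5, "distal_frac": 0.5,
               "line1_rate": 0.04, "n_reads": 12000},
    })
    reference_condition: str = "WT"
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    expression: ExpressionSimConfig = field(default_factory=ExpressionSimConfig)
    n_replicates: int = 3
    replicate_reads: int = 5000
    gap_threshold: int = 10
    utr3_ext: int = 4000
    utr5_ext: int = 1000
    line1_min_length: int = 6000
    n_bins: int = 5
    short_quantile: float = 0.20
    pseudo_signal: float = 1.0
    readthrough_up_window: int = 500
    readthrough_down_window: int = 500
    readthrough_down_offset: int = 500
    background_window: int = 4000

    def validate(self) -> None:
        if len(self.conditions) != 2:
            raise ConfigError("exactly two conditions are required")
        if len(set(self.conditions)) != len(self.conditions):
            raise ConfigError("condition labels must be distinct")
        if self.reference_condition not in self.conditions:
            raise ConfigError(
                f"reference condition {self.reference_condition!r} not in "
                f"{sorted(self.conditions)}"
            )
        positives = {
            "n_replicates": self.n_replicates,
            "replicate_reads": self.replicate_reads,
            "utr3_ext": self.utr3_ext, "utr5_ext": self.utr5_ext,
            "line1_min_length": self.line1_min_length, "n_bins": self.n_bins,
            "pseudo_signal": self.pseudo_signal,
            "readthrough_up_window": self.readthrough_up_window,
            "readthrough_down_window": self.readthrough_down_window,
            "background_window": self.background_window,
        }
        for name, value in positives.items():
            if value <= 0:
                raise ConfigError(f"{name} must be positive (got {value})")
        if self.gap_threshold < 0:
            raise ConfigError("gap_threshold must be >= 0")
        if self.readthrough_down_offset < 0:
            raise ConfigError("readthrough_down_offset must be >= 0")
        if not 0.0 < self.short_quantile < 1.0:
            raise ConfigError("short_quantile must lie in (0, 1)")
        if self.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2 for the RUD t test")


def validate_config(raw) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file path or a raw mapping."""
    if isinstance(raw, (str, Path)):
        with open(raw) as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    unknown = sorted(set(raw) - _TOP_KEYS)
    if unknown:
        raise ConfigError(f"unknown configuration keys: {', '.join(unknown)}")
    kwargs = dict(raw)
    if "conditions" in kwargs:
        conditions = kwargs["conditions"]
        for label, params in conditions.items():
            bad = sorted(set(params) - _CONDITION_KEYS)
            if bad:
                raise ConfigError(
                    f"unknown keys for condition {label!r}: {', '.join(bad)}"
                )
    for section, cls in (("genome", GenomeConfig),
                         ("expression", ExpressionSimConfig)):
        if section in kwargs and isinstance(kwargs[section], dict):
            known = {f.name for f in dataclasses.fields(cls)}
            bad = sorted(set(kwargs[section]) - known)
            if bad:
                raise ConfigError(
                    f"unknown keys in {section!r}: {', '.join(bad)}"
                )
            kwargs[section] = cls(**kwargs[section])
    config = PipelineConfig(**kwargs)
    config.validate()
    return config


@dataclass
class Report:
    tables: Dict[str, pd.DataFrame]
    provenance: Dict[str, object]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        created = not outdir.exists()
        outdir.mkdir(parents=True, exist_ok=True)
        try:
            for key in sorted(self.tables):
                self.tables[key].to_csv(
                    outdir / f"{key}.tsv", sep="\t", index=False,
                    float_format="%.10g",
                )
            payload = {
                "provenance": self.provenance,
                "tables": {
                    key: json.loads(
                        df.to_json(orient="records", double_precision=10)
                    )
                    for key, df in sorted(self.tables.items())
                },
            }
            with open(outdir / "report.json", "w") as fh:
                json.dump(payload, fh, indent=1, sort_keys=True)
        except Exception:
            if created:
                shutil.rmtree(outdir, ignore_errors=True)
            raise


@dataclass
class ConditionResult:
    """Intermediate per-condition products of the main simulation run."""

    label: str
    statuses: dict
    calls: dict
    region_table: object
    coverage: CoverageTrack
    background: float
    repeat_tables: dict
    end_profile: object
    full_length_count: int
    unique_total: int
    readthrough: list
    replicate_ruds: list
    n_reads: int


def _condition_params(config: PipelineConfig, label: str, seed: int,
                      n_reads: Optional[int] = None) -> ConditionParams:
    raw = dict(config.conditions[label])
    reads = n_reads if n_reads is not None else raw.pop("n_reads", 10000)
    raw.pop("n_reads", None)
    return ConditionParams(n_reads=reads, seed=seed, **raw)


def _run_condition(config: PipelineConfig, bundle, label: str,
                   seeds: List[int]) -> ConditionResult:
    index = GeneIndex(bundle.genes, bundle.chrom_lengths,
                      config.utr3_ext, config.utr5_ext)
    apa_genes = [g for g in bundle.genes if g.is_apa]
    non_apa = [g for g in bundle.genes if not g.is_apa]

    params = _condition_params(config, label, seeds[0])
    reads, truths = simulate_reads(bundle, params, read_prefix=label,
                                   utr3_ext=config.utr3_ext,
                                   utr5_ext=config.utr5_ext)
    hits = parse_psl_lines(emit_truth_psl(reads, truths, bundle))
    all_hits: Dict[str, list] = {}
    for hit in hits:
        all_hits.setdefault(hit.read_id, []).append(hit)
    statuses = resolve_all(hits, [r[0] for r in reads], config.gap_threshold)

    calls = {}
    for read_id, status in statuses.items():
        if status.status == STATUS_UNIQUE:
            h = status.best_hit
            calls[read_id] = classify_read(h.blocks, index, h.chrom, read_id)
    region_table = tabulate_regions(list(calls.values()), label)

    unique_hits = [s.best_hit for s in statuses.values()
                   if s.status == STATUS_UNIQUE]
    coverage = CoverageTrack.from_hits(unique_hits, bundle.chrom_lengths)
    background = sample_background(non_apa, coverage, config.background_window)

    repeat_tables = attribute_repeats(statuses, calls, bundle.repeats, label,
                                      all_hits)
    unmapped_reads = [
        (rid, seq) for rid, seq in reads
        if statuses[rid].status == STATUS_UNMAPPED
    ]
    repeat_tables["unmapped"] = attribute_unmapped(
        unmapped_reads, bundle.consensus, label
    )

    pairs = line1_full_length_filter(unique_hits, bundle.repeats,
                                     config.line1_min_length)
    profile = line1_end_profile(pairs, label, config.n_bins)

    readthrough = [
        readthrough_index(g, coverage, config.readthrough_up_window,
                          config.readthrough_down_window,
                          config.readthrough_down_offset)
        for g in apa_genes
    ]

    replicate_ruds = []
    for j, rep_seed in enumerate(seeds[1:]):
        rep_params = _condition_params(config, label, rep_seed,
                                       n_reads=config.replicate_reads)
        rep_reads, rep_truths = simulate_reads(
            bundle, rep_params, read_prefix=f"{label}r{j}",
            utr3_ext=config.utr3_ext, utr5_ext=config.utr5_ext,
        )
        rep_hits = parse_psl_lines(emit_truth_psl(rep_reads, rep_truths,
                                                  bundle))
        rep_statuses = resolve_all(rep_hits, [r[0] for r in rep_reads],
                                   config.gap_threshold)
        rep_cov = CoverageTrack.from_hits(
            [s.best_hit for s in rep_statuses.values()
             if s.status == STATUS_UNIQUE],
            bundle.chrom_lengths,
        )
        rep_bg = sample_background(non_apa, rep_cov, config.background_window)
        records = [gene_rud(g, rep_cov, rep_bg) for g in apa_genes]
        replicate_ruds.append(sample_rud(records, f"{label}_rep{j}", rep_bg))

    return ConditionResult(
        label=label, statuses=statuses, calls=calls,
        region_table=region_table, coverage=coverage, background=background,
        repeat_tables=repeat_tables, end_profile=profile,
        full_length_count=len(pairs), unique_total=len(unique_hits),
        readthrough=readthrough, replicate_ruds=replicate_ruds,
        n_reads=params.n_reads,
    )


def run_pipeline(config: PipelineConfig, outdir=None) -> Report:
    """Run every stage in dependency order and assemble the report."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    n_cond_seeds = 1 + config.n_replicates
    state = ss.generate_state(2 + 2 * n_cond_seeds) & 0x7FFFFFFF
    genome_seed, expr_seed = int(state[0]), int(state[1])
    cond_seed_blocks = [
        [int(s) for s in state[2 + i * n_cond_seeds:
                              2 + (i + 1) * n_cond_seeds]]
        for i in range(2)
    ]

    ref_label = config.reference_condition
    alt_label = next(l for l in config.conditions if l != ref_label)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(name, exc) from exc

    bundle = stage("genome", build_toy_genome,
                   replace(config.genome, seed=genome_seed))
    ref = stage(f"condition:{ref_label}", _run_condition, config, bundle,
                ref_label, cond_seed_blocks[0])
    alt = stage(f"condition:{alt_label}", _run_condition, config, bundle,
                alt_label, cond_seed_blocks[1])

    tables: Dict[str, pd.DataFrame] = {}

    # fig1b: mapping uniqueness
    def mapping_row(res):
        counts = {STATUS_UNIQUE: 0, STATUS_NON_UNIQUE: 0, STATUS_UNMAPPED: 0}
        for st in res.statuses.values():
            counts[st.status] += 1
        total = sum(counts.values())
        return counts, total

    ref_counts, ref_total = mapping_row(ref)
    alt_counts, alt_total = mapping_row(alt)
    fisher_p = stage("fig1b", fisher_exact_2x2, [
        [ref_counts[STATUS_UNIQUE], ref_total - ref_counts[STATUS_UNIQUE]],
        [alt_counts[STATUS_UNIQUE], alt_total - alt_counts[STATUS_UNIQUE]],
    ])
    tables["fig1b"] = pd.DataFrame([
        {"condition": lab, "total": tot, "unique": c[STATUS_UNIQUE],
         "non_unique": c[STATUS_NON_UNIQUE], "unmapped": c[STATUS_UNMAPPED],
         "pct_unique": 100.0 * c[STATUS_UNIQUE] / tot,
         "fisher_p_unique": fisher_p}
        for lab, c, tot in ((ref_label, ref_counts, ref_total),
                            (alt_label, alt_counts, alt_total))
    ])

    # fig1c: region categories, exon as control
    comparisons = stage("fig1c", compare_region_tables,
                        ref.region_table, alt.region_table)
    rows = [{
        "category": "exon",
        "count_a": ref.region_table.counts["exon"],
        "count_b": alt.region_table.counts["exon"],
        "prop_a": ref.region_table.proportions["exon"],
        "prop_b": alt.region_table.proportions["exon"],
        "ratio": (alt.region_table.proportions["exon"]
                  / ref.region_table.proportions["exon"]),
        "fisher_p": float("nan"),
    }]
    rows += [dataclasses.asdict(c) for c in comparisons]
    fig1c = pd.DataFrame(rows)
    tables["fig1c"] = fig1c.drop(columns=["degenerate"], errors="ignore")

    # fig2: replicate mean RUD + Welch t test
    welch = stage("fig2", welch_t_test,
                  [s.mean_rud for s in ref.replicate_ruds],
                  [s.mean_rud for s in alt.replicate_ruds])
    tables["fig2"] = pd.DataFrame([
        {"condition": s.label.rsplit("_rep", 1)[0], "replicate": i,
         "mean_rud": s.mean_rud, "sd_genes": s.sd, "n_genes": s.n_genes,
         "background": s.background, "welch_p": welch.pvalue}
        for res in (ref, alt)
        for i, s in enumerate(res.replicate_ruds)
    ])

    # fig3a: stratified expression changes
    def fig3a():
        gene_info, expr_a, expr_b = simulate_expression(
            replace(config.expression, seed=expr_seed)
        )
        cutoff, strata = stratify_genes(gene_info, config.short_quantile)
        changes, n_excluded = expression_changes(expr_a, expr_b,
                                                 config.pseudo_signal)
        _groups, ks_results, excluded = cdf_compare(changes, strata)
        sizes = strata.groupby("stratum").size().to_dict()
        ks_df = pd.DataFrame([
            {"stratum_a": k.stratum_a, "stratum_b": k.stratum_b,
             "n_a": k.n_a, "n_b": k.n_b, "ks_d": k.statistic,
             "ks_p": k.pvalue, "length_cutoff": cutoff}
            for k in ks_results
        ])
        strata_df = pd.DataFrame([
            {"stratum": s, "n_genes": sizes.get(s, 0)}
            for s in sorted(sizes)
        ])
        return ks_df, strata_df, n_excluded

    ks_df, strata_df, n_excluded = stage("fig3a", fig3a)
    tables["fig3a"] = ks_df
    tables["fig3a_strata"] = strata_df

    # fig3d: per-gene read-through normalized to the reference
    normalized = stage("fig3d", normalize_readthrough, alt.readthrough,
                       ref.readthrough)
    tables["fig3d"] = pd.DataFrame([
        {"gene_id": n.gene_id,
         "ratio_ref": np.nan if n.reference_ratio is None else n.reference_ratio,
         "ratio_alt": np.nan if n.ratio is None else n.ratio,
         "normalized_fold": np.nan if n.normalized_fold is None
         else n.normalized_fold}
        for n in normalized
    ])

    # fig4a-d: repeat fold changes per read category
    panel_keys = {"fig4a": "intergenic_unique", "fig4b": "intronic_unique",
                  "fig4c": "non_unique", "fig4d": "unmapped"}
    for key, cat in panel_keys.items():
        def folds(cat=cat):
            rows = []
            for cls in REPEAT_CLASSES:
                fc = repeat_fold_change(ref.repeat_tables[cat],
                                        alt.repeat_tables[cat], cls)
                rows.append(dataclasses.asdict(fc))
            return pd.DataFrame(rows)

        tables[key] = stage(key, folds)

    # fig4e: full-length LINE-1 proportion of uniquely mapped reads
    def fig4e():
        pa = ref.full_length_count / ref.unique_total
        pb = alt.full_length_count / alt.unique_total
        p = fisher_exact_2x2([
            [ref.full_length_count, ref.unique_total - ref.full_length_count],
            [alt.full_length_count, alt.unique_total - alt.full_length_count],
        ])
        fold = pb / pa if pa > 0 else float("inf")
        return pd.DataFrame([
            {"condition": ref_label, "full_length_reads": ref.full_length_count,
             "unique_reads": ref.unique_total, "pct": 100 * pa,
             "sd": proportion_sd(pa, ref.unique_total), "fold": fold,
             "fisher_p": p},
            {"condition": alt_label, "full_length_reads": alt.full_length_count,
             "unique_reads": alt.unique_total, "pct": 100 * pb,
             "sd": proportion_sd(pb, alt.unique_total), "fold": fold,
             "fisher_p": p},
        ])

    tables["fig4e"] = stage("fig4e", fig4e)

    # fig4f: LINE-1 3'-end bin profile
    chi = stage("fig4f", compare_end_profiles, ref.end_profile,
                alt.end_profile)
    tables["fig4f"] = pd.DataFrame([
        {"condition": res.end_profile.condition,
         **{f"bin{i + 1}": c
            for i, c in enumerate(res.end_profile.bin_counts)},
         "n_reads": res.end_profile.n_reads, "chi2": chi.statistic,
         "df": chi.df, "p": chi.pvalue}
        for res in (ref, alt)
    ])

    config_dict = dataclasses.asdict(config)
    config_json = json.dumps(config_dict, sort_keys=True, default=str)
    provenance = {
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": config.seed,
        "version": __version__,
        "read_accounting": {
            res.label: {
                "simulated": res.n_reads,
                "unique": res.unique_total,
                "classified": len(res.calls),
                "non_unique": sum(
                    1 for s in res.statuses.values()
                    if s.status == STATUS_NON_UNIQUE
                ),
                "unmapped": sum(
                    1 for s in res.statuses.values()
                    if s.status == STATUS_UNMAPPED
                ),
            }
            for res in (ref, alt)
        },
        "expression_genes_excluded": n_excluded,
    }
    for label, acc in provenance["read_accounting"].items():
        if acc["unique"] + acc["non_unique"] + acc["unmapped"] != acc["simulated"]:
            raise PipelineError(
                "accounting",
                RuntimeError(f"reads lost in condition {label}: {acc}"),
            )

    report = Report(tables=tables, provenance=provenance)
    if outdir is not None:
        report.write(outdir)
    return report
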