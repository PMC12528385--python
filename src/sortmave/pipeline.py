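"""End-to-end orchestration: config, barcode counting, full pipeline runs.

``run_pipeline`` drives the whole analysis on either simulated or supplied
count tables: scoring every assay/replicate, bootstrap FDRs, expression-score
merging, regional window statistics, selective-sensitivity calls and (on
simulated data) a severity-ordered synthetic patient cohort with ROC
evaluation.  Every output directory receives a machine-readable
``manifest.json`` echoing the full configuration, its hash and the seeds, so
a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .library_design import INSR_ECTODOMAIN, Region, enumerate_possible_variants
from .scoring import DEFAULT_BIN_WEIGHTS, score_assay
from .fdr import DEFAULT_N_BOOT, add_fdr
from .integration import merge_expression_score, write_mavedb_scores
from .regional import significant_intervals, sliding_window_test
from .translational import (
    SENSITIVITY_THRESHOLD,
    classify_quadrants,
    select_robust_lof,
    sensitivity_table,
)
from .diagnostics import roc_auc, roc_curve as roc_points, score_cohort, simulate_patient_cohort
from . import synthetic_data as sd

__all__ = ["PipelineConfig", "count_barcode_reads", "run_pipeline"]

log = logging.getLogger("sortmave")


@dataclass
class PipelineConfig:
    """All thresholds and knobs of a pipeline run, in one place."""

    region_start: int = INSR_ECTODOMAIN.start_pos
    region_end: int = INSR_ECTODOMAIN.end_pos
    n_variants: int = 500
    barcodes_per_variant: int = 2
    wt_barcode_fraction: float = 0.35
    replicates: dict = field(default_factory=lambda: dict(sd.DEFAULT_REPLICATES))
    min_reads: int = 150
    bin_weights: tuple = DEFAULT_BIN_WEIGHTS
    wt_policy: str = "wt_or_synonymous"
    min_replicates_binding: int = 2
    min_replicates_signalling: int = 3
    n_boot: int = DEFAULT_N_BOOT
    window: int = 15
    min_variants_per_window: int = 5
    sensitivity_threshold: float = SENSITIVITY_THRESHOLD
    epitope_exceptions: list = field(default_factory=list)
    reads_per_bin: int = 100_000
    cells_per_barcode_mean: float = 400.0
    cell_noise_sd: float = 1.0
    seed: int = 0

    @property
    def region(self) -> Region:
        return Region(self.region_start, self.region_end)

    def min_replicates(self, assay: str) -> int:
        return (
            self.min_replicates_signalling
            if assay.startswith("sig")
            else self.min_replicates_binding
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bin_weights"] = list(d["bin_weights"])
        d["epitope_exceptions"] = [list(e) for e in d["epitope_exceptions"]]
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.bin_weights = tuple(cfg.bin_weights)
        cfg.epitope_exceptions = [tuple(e) for e in cfg.epitope_exceptions]
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def count_barcode_reads(
    reads: Iterable[Mapping[str, Iterable[str]]] | Mapping[str, Iterable[str]],
    bvmap: pd.DataFrame,
    barcode_length: int = 30,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Exact-match barcode counting from per-bin read sequences.

    ``reads`` maps bin name (``bin1``..``bin4``) to an iterable of read
    sequences; a read is assigned to a map barcode when its first
    ``barcode_length`` characters match exactly, otherwise it is tallied as
    unmatched.  Returns ``(BinCountTable, unmatched_per_bin)``; matched plus
    unmatched always equals the number of input reads.
    """
    if bvmap.empty:
        raise ValueError("empty barcode-variant map")
    barcodes = bvmap["barcode"].tolist()
    index = {bc: i for i, bc in enumerate(barcodes)}
    counts = np.zeros((len(barcodes), 4), dtype=int)
    unmatched: dict[str, int] = {}
    bins = ["bin1", "bin2", "bin3", "bin4"]
    for j, bin_name in enumerate(bins):
        miss = 0
        for read in reads.get(bin_name, []):
            i = index.get(read[:barcode_length])
            if i is None:
                miss += 1
            else:
                counts[i, j] += 1
        unmatched[bin_name] = miss
    table = pd.DataFrame({"barcode": barcodes})
    table[bins] = counts
    return table, unmatched


def read_fastq_sequences(path) -> list[str]:
    """Sequence lines of a FASTQ file (qualities ignored; counting is
    exact-match)."""
    from Bio import SeqIO

    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]


def _simulate_inputs(config: PipelineConfig):
    region = config.region
    wt_seq = sd.random_protein_sequence(len(region), config.seed, region.start_pos)
    all_variants = enumerate_possible_variants(region, wt_seq)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5E1]))
    chosen = rng.choice(len(all_variants), size=config.n_variants, replace=False)
    variants = [all_variants[i] for i in sorted(chosen)]
    # make sure the planted controls exist in the simulated library
    by_id = {v.id: v for v in all_variants}
    for vid, per_assay in sd.CONTROL_EFFECTS.items():
        pos = int(vid[1:-1])
        if region.start_pos <= pos <= region.end_pos:
            control = sd.VariantSpec(pos, wt_seq[pos - region.start_pos], vid[-1])
            if control.klass == "missense" and control not in variants:
                variants.append(control)
    effects = sd.sample_true_effects(variants, seed=config.seed)
    controls = {
        vid: eff
        for vid, eff in sd.CONTROL_EFFECTS.items()
        if vid in set(effects["variant"])
    }
    if controls:
        effects = sd.plant_controls(effects, controls)
    bvmap = sd.build_barcode_variant_map(
        effects,
        config.barcodes_per_variant,
        config.wt_barcode_fraction,
        config.seed,
    )
    sim = sd.SortSimConfig(
        cell_noise_sd=config.cell_noise_sd,
        cells_per_barcode_mean=config.cells_per_barcode_mean,
        reads_per_bin=config.reads_per_bin,
        barcodes_per_variant=config.barcodes_per_variant,
        wt_barcode_fraction=config.wt_barcode_fraction,
        replicates=config.replicates,
        seed=config.seed,
    )
    counts = sd.simulate_experiment(effects, bvmap, sim)
    return wt_seq, effects, bvmap, counts


def run_pipeline(
    config: PipelineConfig,
    outdir,
    counts: Mapping[str, Mapping[int, pd.DataFrame]] | None = None,
    bvmap: pd.DataFrame | None = None,
) -> dict:
    """Run the full analysis; returns the in-memory result bundle.

    With ``counts=None`` a synthetic experiment is simulated from the config
    seed (and the latent truth is kept in the bundle for validation).  Output
    tables are written as TSV/CSV under ``outdir`` together with a manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config}
    log.info("pipeline start: config hash %s", config.config_hash())
    for key, value in sorted(config.to_dict().items()):
        log.info("config %s = %r", key, value)

    if counts is None:
        wt_seq, effects, bvmap, counts = _simulate_inputs(config)
        bundle["wt_sequence"] = wt_seq
        bundle["true_effects"] = effects
        effects.to_csv(outdir / "true_effects.tsv", sep="\t", index=False)
    elif bvmap is None:
        raise ValueError("supplied counts need a barcode-variant map")
    bundle["bvmap"] = bvmap

    # --- score every assay, attach FDRs ------------------------------------
    tables: dict[str, pd.DataFrame] = {}
    barcode_scores: dict[str, dict[int, pd.DataFrame]] = {}
    for assay, reps in counts.items():
        table, btables = score_assay(
            reps,
            bvmap,
            min_reads=config.min_reads,
            weights=config.bin_weights,
            wt_policy=config.wt_policy,
            min_replicates=config.min_replicates(assay),
        )
        table = add_fdr(
            table, btables, bvmap,
            n_boot=config.n_boot, seed=config.seed, wt_policy=config.wt_policy,
        )
        tables[assay] = table
        barcode_scores[assay] = btables
        write_mavedb_scores(table, outdir / f"scores_{assay}.csv")
        table.to_csv(outdir / f"variant_scores_{assay}.tsv", sep="\t", index=False)
        log.info("scored %s: %d variants", assay, len(table))
    bundle["scores"] = tables
    bundle["barcode_scores"] = barcode_scores

    # --- effect matrix (heatmap layout) for the insulin binding assay --------
    if "wt_sequence" in bundle and "bind_insulin" in tables:
        from .integration import build_effect_matrix

        matrix, wt_mask = build_effect_matrix(
            tables["bind_insulin"], config.region, bundle["wt_sequence"]
        )
        matrix.to_csv(outdir / "effect_matrix_bind_insulin.tsv", sep="\t")
        bundle["effect_matrix"] = (matrix, wt_mask)

    # --- expression score from the two antibody binding assays --------------
    if {"bind_83_7", "bind_83_14"} <= set(tables):
        expression = merge_expression_score(
            tables["bind_83_7"], tables["bind_83_14"], config.epitope_exceptions
        )
        tables["expression"] = expression
        expression.to_csv(outdir / "variant_scores_expression.tsv", sep="\t", index=False)
        log.info("merged expression score: %d variants", len(expression))

    # --- regional comparison: insulin binding vs expression ------------------
    if {"bind_insulin", "expression"} <= set(tables):
        windows = sliding_window_test(
            tables["bind_insulin"],
            tables["expression"],
            window=config.window,
            min_variants=config.min_variants_per_window,
        )
        windows.to_csv(outdir / "windows_binding_vs_expression.tsv", sep="\t", index=False)
        bundle["windows"] = windows
        bundle["window_intervals"] = significant_intervals(windows)

    # --- antibody activatability --------------------------------------------
    ab_sigs = {m: tables[f"sig_{m.replace('-', '_')}"]
               for m in ("83-7", "83-14")
               if f"sig_{m.replace('-', '_')}" in tables}
    if "sig_insulin" in tables and len(ab_sigs) == 2:
        try:
            robust = select_robust_lof(tables["sig_insulin"], ab_sigs)
        except ValueError:
            robust = pd.Index([])
        sens = sensitivity_table(
            tables["sig_insulin"], ab_sigs, robust, config.sensitivity_threshold
        )
        sens, proportions = classify_quadrants(
            sens, threshold=config.sensitivity_threshold
        )
        sens.to_csv(outdir / "selective_sensitivity.tsv", sep="\t", index=False)
        bundle["sensitivity"] = sens
        bundle["quadrant_proportions"] = proportions
        log.info("robust LoF variants: %d", len(robust))

    # --- synthetic diagnostic cohort (simulation mode only) ------------------
    if "true_effects" in bundle and {"bind_insulin", "sig_insulin", "expression"} <= set(tables):
        assay_tables = {
            "expression": tables["expression"],
            "bind_insulin": tables["bind_insulin"],
            "sig_insulin": tables["sig_insulin"],
        }
        patients = simulate_patient_cohort(assay_tables, seed=config.seed)
        cohort = score_cohort(patients, assay_tables)
        cohort.to_csv(outdir / "cohort_scores.tsv", sep="\t", index=False)
        labelled = cohort[cohort["phenotype"].isin(["DS", "RMS", "TA", "benign"])]
        labels = (labelled["phenotype"] != "benign").astype(int)
        auc = roc_auc(labelled["composite_sum"], labels)
        points = roc_points(labelled["composite_sum"], labels)
        points.to_csv(outdir / "roc_composite_sum.tsv", sep="\t", index=False)
        bundle["cohort"] = cohort
        bundle["cohort_auc"] = auc
        log.info("cohort ROC AUC (composite sum): %.3f", auc)

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle["manifest"] = manifest
    return bundle
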