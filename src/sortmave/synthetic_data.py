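"""Seeded generative model of the sort-seq experiment.

Emulates the structure of a four-bin FACS sort of a barcoded variant library:
each barcode tags a clonal cell population whose latent fluorescence is the
variant's assay-specific effect plus Normal cell-to-cell noise; cells fall
into four bins at fixed gates; sequencing draws a fixed number of reads per
bin, multinomially over barcodes in proportion to the sorted cell counts.

The generated libraries reproduce the qualitative features the scoring
pipeline relies on: wild-type and synonymous barcodes centred on the WT mean,
missense effects skewed low (about 32 % loss-of-function and 7 %
gain-of-function per assay by default), stop-codon barcodes globally depleted
in read counts (antibiotic selection removes most truncating clones), several
barcodes per variant, several replicates per assay, and planted control
variants: A119V and S350L lose expression and binding, while D734A loses
insulin binding and insulin-stimulated signalling with normal surface
expression and antibody responsiveness.

Everything is deterministic given the global seed; per-(assay, replicate)
substreams are derived with ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .library_design import (
    AMINO_ACIDS,
    STOP,
    SYNONYMOUS,
    Region,
    VariantSpec,
    classify_variant,
)

__all__ = [
    "ASSAYS",
    "DEFAULT_REPLICATES",
    "EffectConfig",
    "SortSimConfig",
    "random_protein_sequence",
    "sample_true_effects",
    "plant_controls",
    "build_barcode_variant_map",
    "simulate_sort_counts",
    "simulate_experiment",
]

#: Assay labels of the six sort-seq screens (binding and pAKT signalling,
#: each stimulated by insulin or one of the two anti-receptor mAbs).
ASSAYS: tuple[str, ...] = (
    "bind_insulin",
    "bind_83_7",
    "bind_83_14",
    "sig_insulin",
    "sig_83_7",
    "sig_83_14",
)

#: Replicate sorts per assay: five for insulin signalling, three elsewhere,
#: matching the replicate structure the downstream filters expect.
DEFAULT_REPLICATES: dict[str, int] = {
    "bind_insulin": 3,
    "bind_83_7": 3,
    "bind_83_14": 3,
    "sig_insulin": 5,
    "sig_83_7": 3,
    "sig_83_14": 3,
}

#: Planted control variants and the assays in which they lose function.
#: A119V and S350L lose surface expression (hence every binding and
#: signalling readout); D734A selectively loses insulin binding and
#: insulin-stimulated signalling but expresses and responds to antibodies.
CONTROL_EFFECTS: dict[str, dict[str, float]] = {
    "A119V": {assay: -2.5 for assay in ASSAYS},
    "S350L": {assay: -2.5 for assay in ASSAYS},
    "D734A": {
        "bind_insulin": -3.0,
        "sig_insulin": -3.0,
        "bind_83_7": 0.0,
        "bind_83_14": 0.0,
        "sig_83_7": 0.0,
        "sig_83_14": 0.0,
    },
}


@dataclass(frozen=True)
class EffectConfig:
    """Mixture model for latent per-variant, per-assay effects.

    A missense variant is loss-of-function with probability ``lof_fraction``
    (effect drawn uniformly from ``lof_range``), gain-of-function with
    probability ``gof_fraction`` (uniform over ``gof_range``), otherwise null
    (effect 0).  Fractions default to the observed per-assay proportions of
    variants decreasing (~32 %) or increasing (~7 %) function.  The class is
    drawn once per variant and shared across assays; effect magnitudes are
    redrawn per assay.  Stop codons are loss-of-function in every assay and
    additionally depleted in abundance by ``stop_abundance``.
    """

    lof_fraction: float = 0.32
    gof_fraction: float = 0.07
    lof_range: tuple[float, float] = (-2.5, -0.5)
    gof_range: tuple[float, float] = (0.3, 1.0)
    nonsense_effect: float = -2.5
    stop_abundance: float = 0.05

    def __post_init__(self) -> None:
        for f in (self.lof_fraction, self.gof_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("mixture fractions must lie in [0, 1]")
        if self.lof_fraction + self.gof_fraction > 1.0:
            raise ValueError("mixture fractions sum to more than 1")


@dataclass(frozen=True)
class SortSimConfig:
    """Tunable knobs of the simulated sort.

    gates
        Three strictly increasing latent-fluorescence thresholds splitting
        cells into four bins; defaults are the quartiles of the WT latent
        distribution N(0, cell_noise_sd).
    cell_noise_sd
        Cell-to-cell standard deviation of latent fluorescence (arbitrary
        linear units; the WT mean is 0).
    cells_per_barcode_mean
        Poisson mean of the number of cells carrying each barcode.
    reads_per_bin
        Fixed sequencing depth per bin (bin frequencies are depth-invariant
        in expectation).
    overdispersion
        Optional Dirichlet-multinomial read noise; ``None`` (default) gives
        plain multinomial reads, a positive float is the Dirichlet
        concentration multiplier (smaller = noisier).
    """

    gates: tuple[float, float, float] | None = None
    cell_noise_sd: float = 1.0
    cells_per_barcode_mean: float = 400.0
    reads_per_bin: int = 100_000
    barcodes_per_variant: int = 2
    wt_barcode_fraction: float = 0.35
    replicates: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_REPLICATES)
    )
    overdispersion: float | None = None
    seed: int = 0

    def resolved_gates(self) -> np.ndarray:
        from scipy.stats import norm

        if self.gates is None:
            g = norm.ppf([0.25, 0.5, 0.75], loc=0.0, scale=self.cell_noise_sd)
        else:
            g = np.asarray(self.gates, dtype=float)
        if not np.all(np.diff(g) > 0):
            raise ValueError("gates must be strictly increasing")
        return g


def random_protein_sequence(
    length: int, seed: int = 0, start_pos: int = 28, pin_controls: bool = True
) -> str:
    """Deterministic pseudo-random wild-type amino-acid sequence.

    With ``pin_controls`` (default) the wild-type residues at the planted
    control positions are fixed (A119, S350, D734) so that the control
    variants A119V, S350L and D734A exist in any region covering them.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA17]))
    seq = list(rng.choice(list(AMINO_ACIDS), size=length))
    if pin_controls:
        for vid in CONTROL_EFFECTS:
            pos, wt = int(vid[1:-1]), vid[0]
            idx = pos - start_pos
            if 0 <= idx < length:
                seq[idx] = wt
    return "".join(seq)


def _variant_frame(variants: Iterable[VariantSpec]) -> pd.DataFrame:
    rows = [
        {
            "variant": v.id,
            "position": v.position,
            "wt_aa": v.wt_aa,
            "alt_aa": v.alt,
            "klass": v.klass,
        }
        for v in variants
    ]
    return pd.DataFrame(rows)


def sample_true_effects(
    variants: Sequence[VariantSpec],
    config: EffectConfig = EffectConfig(),
    assays: Sequence[str] = ASSAYS,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw the latent effect table (one row per variant).

    Returns a DataFrame with columns ``variant, position, wt_aa, alt_aa,
    klass, abundance`` plus one effect column per assay (named
    ``effect_<assay>``).  Wild-type and synonymous variants have effect 0 in
    every assay and abundance 1; nonsense variants have ``nonsense_effect``
    everywhere and abundance ``stop_abundance``.
    """
    frame = _variant_frame(variants)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xEFF]))
    n = len(frame)
    u = rng.uniform(size=n)
    is_mis = (frame["klass"] == "missense").to_numpy()
    is_stop = (frame["klass"] == "nonsense").to_numpy()
    lof = is_mis & (u < config.lof_fraction)
    gof = is_mis & ~lof & (u < config.lof_fraction + config.gof_fraction)

    for assay in assays:
        eff = np.zeros(n)
        eff[lof] = rng.uniform(*config.lof_range, size=int(lof.sum()))
        eff[gof] = rng.uniform(*config.gof_range, size=int(gof.sum()))
        eff[is_stop] = config.nonsense_effect
        frame[f"effect_{assay}"] = eff
    frame["abundance"] = np.where(is_stop, config.stop_abundance, 1.0)
    return frame


def plant_controls(
    effects: pd.DataFrame,
    controls: Mapping[str, Mapping[str, float]] = CONTROL_EFFECTS,
) -> pd.DataFrame:
    """Overwrite the latent effects of the planted control variants.

    Raises ``KeyError`` if a control variant is absent from the effect table;
    variants not listed in ``controls`` are untouched.
    """
    out = effects.copy()
    index = pd.Index(out["variant"])
    for variant_id, per_assay in controls.items():
        locs = index.get_indexer_for([variant_id])
        locs = locs[locs >= 0]
        if len(locs) == 0:
            raise KeyError(f"control variant {variant_id} not in effect table")
        for assay, value in per_assay.items():
            col = f"effect_{assay}"
            if col in out.columns:
                out.iloc[locs, out.columns.get_loc(col)] = value
    return out


def _random_barcodes(n: int, rng: np.random.Generator, length: int = 30) -> list[str]:
    letters = np.array(list("ACGT"))
    # 30-mers drawn uniformly; collisions at these n are vanishingly rare but
    # regenerate duplicates to keep the map key unique.
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        block = letters[rng.integers(0, 4, size=(n - len(out), length))]
        for row in block:
            bc = "".join(row)
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return out


def build_barcode_variant_map(
    effects: pd.DataFrame,
    barcodes_per_variant: int = 2,
    wt_barcode_fraction: float = 0.35,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign random 30-mer barcodes to each variant plus a WT reference pool.

    ``wt_barcode_fraction`` is the fraction of all barcodes tagging unmutated
    (wild-type) clones, mirroring the large WT complement of real libraries.
    Support reads (long-read coverage) are Poisson(19) + 1 per barcode.
    """
    if not 0.0 <= wt_barcode_fraction < 1.0:
        raise ValueError("wt_barcode_fraction must lie in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBC]))
    n_var = len(effects)
    n_var_bc = n_var * barcodes_per_variant
    n_wt = int(round(n_var_bc * wt_barcode_fraction / (1.0 - wt_barcode_fraction)))
    barcodes = _random_barcodes(n_var_bc + n_wt, rng)
    rows = pd.DataFrame(
        {
            "barcode": barcodes,
            "position": np.concatenate(
                [np.repeat(effects["position"].to_numpy(), barcodes_per_variant),
                 np.zeros(n_wt, dtype=int)]
            ),
            "wt_aa": list(np.repeat(effects["wt_aa"].to_numpy(), barcodes_per_variant))
            + [SYNONYMOUS] * n_wt,
            "alt_aa": list(np.repeat(effects["alt_aa"].to_numpy(), barcodes_per_variant))
            + [SYNONYMOUS] * n_wt,
            "support_reads": rng.poisson(19, size=n_var_bc + n_wt) + 1,
        }
    )
    return rows


def _substream(seed: int, assay: str, replicate: int) -> np.random.Generator:
    # process-independent substream key (Python's hash() is salted per run)
    assay_key = zlib.crc32(assay.encode("ascii")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([seed, assay_key, replicate]))


def simulate_sort_counts(
    effects: pd.DataFrame,
    bvmap: pd.DataFrame,
    config: SortSimConfig,
    assay: str,
    replicate: int,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate one (assay, replicate) four-bin barcode count table.

    Per barcode the cell count is Poisson(cells_per_barcode_mean x abundance);
    cells land in bins with the Normal-CDF gate probabilities implied by the
    variant's latent effect (equivalent to drawing each cell's fluorescence
    individually); each bin is then sequenced to exactly ``reads_per_bin``
    reads, multinomially over barcodes proportional to sorted cell counts.

    Returns a DataFrame with columns ``barcode, bin1..bin4``; per-bin counts
    sum exactly to ``reads_per_bin`` whenever any cells were sorted into the
    bin.
    """
    from scipy.stats import norm

    gates = config.resolved_gates()
    rng = _substream(config.seed if seed is None else seed, assay, replicate)

    eff_col = f"effect_{assay}"
    if eff_col not in effects.columns:
        raise KeyError(f"no effects for assay {assay!r}")
    lookup = effects.set_index("variant")
    from .library_design import variant_ids

    ids = variant_ids(bvmap)
    known = ids.isin(lookup.index) | ids.eq("WT")
    if not known.all():
        raise KeyError("barcode-variant map contains variants without effects")
    e = np.where(ids.eq("WT"), 0.0, lookup[eff_col].reindex(ids).fillna(0.0))
    abundance = np.where(
        ids.eq("WT"), 1.0, lookup["abundance"].reindex(ids).fillna(1.0)
    )

    n_cells = rng.poisson(config.cells_per_barcode_mean * abundance)
    # P(bin j) from the Normal CDF between gates
    z = (gates[None, :] - e[:, None]) / config.cell_noise_sd
    cdf = norm.cdf(z)
    probs = np.diff(np.concatenate(
        [np.zeros((len(e), 1)), cdf, np.ones((len(e), 1))], axis=1), axis=1)
    sorted_cells = rng.multinomial(n_cells, probs)  # barcodes x 4

    counts = np.zeros_like(sorted_cells)
    for j in range(4):
        col = sorted_cells[:, j].astype(float)
        total = col.sum()
        if total == 0:
            continue
        p = col / total
        if config.overdispersion is not None:
            p = rng.dirichlet(np.maximum(p * config.overdispersion, 1e-12))
        counts[:, j] = rng.multinomial(config.reads_per_bin, p)
    return pd.DataFrame(
        {
            "barcode": bvmap["barcode"].to_numpy(),
            "bin1": counts[:, 0],
            "bin2": counts[:, 1],
            "bin3": counts[:, 2],
            "bin4": counts[:, 3],
        }
    )


def simulate_experiment(
    effects: pd.DataFrame,
    bvmap: pd.DataFrame,
    config: SortSimConfig,
    assays: Sequence[str] | None = None,
) -> dict[str, dict[int, pd.DataFrame]]:
    """Simulate every (assay, replicate) count table of the experiment."""
    assays = tuple(assays) if assays is not None else tuple(config.replicates)
    out: dict[str, dict[int, pd.DataFrame]] = {}
    for assay in assays:
        out[assay] = {
            rep: simulate_sort_counts(effects, bvmap, config, assay, rep)
            for rep in range(1, config.replicates[assay] + 1)
        }
    return out
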