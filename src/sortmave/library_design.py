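"""Saturation-mutagenesis library design and barcode-variant map hygiene.

The mutagenised target is the extracellular domain of the human insulin
receptor (INSR, B isoform), residues 28-955 of the preproprotein: 928 codons,
each replaced by an NNS degenerate codon (N = any base, S = G/C) so that every
position can carry all 20 amino acids plus one stop codon (TAG).  Clones are
tagged with random 30-mer DNA barcodes; long-read sequencing phases barcodes
with variants, and this module implements the arithmetic of the design plus
the collision rule that removes near-identical barcodes assigned to different
variants.

Coordinates are 1-based inclusive residue positions of the INSR-B
preproprotein (signal peptide included).  Nucleotide-level coordinates are not
modelled.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "AMINO_ACIDS",
    "STOP",
    "SYNONYMOUS",
    "Region",
    "VariantSpec",
    "INSR_ECTODOMAIN",
    "classify_variant",
    "region_codon_count",
    "enumerate_possible_variants",
    "nns_codon_outcomes",
    "plan_mutagenesis_pools",
    "filter_barcode_collisions",
    "read_barcode_variant_map",
    "write_barcode_variant_map",
]

#: The 20 proteinogenic amino acids, one-letter codes, alphabetical.
AMINO_ACIDS: tuple[str, ...] = tuple(sorted("ACDEFGHIKLMNPQRSTVWY"))

#: Symbol used for a stop (nonsense) outcome in variant tables.
STOP = "*"

#: Symbol used for a synonymous (amino-acid-preserving) outcome.
SYNONYMOUS = "="

_MAP_COLUMNS = ["barcode", "position", "wt_aa", "alt_aa", "support_reads"]


class InvalidRegionError(ValueError):
    """Raised when a residue region has start > end."""


@dataclass(frozen=True, order=True)
class Region:
    """A contiguous run of residues, 1-based inclusive on both ends."""

    start_pos: int
    end_pos: int

    def __post_init__(self) -> None:
        if self.start_pos > self.end_pos:
            raise InvalidRegionError(
                f"start_pos {self.start_pos} > end_pos {self.end_pos}"
            )
        if self.start_pos < 1:
            raise InvalidRegionError("residue numbering is 1-based")

    def __len__(self) -> int:
        return self.end_pos - self.start_pos + 1

    @property
    def positions(self) -> range:
        return range(self.start_pos, self.end_pos + 1)


#: The mutagenised INSR ectodomain: mature-receptor start to transmembrane start.
INSR_ECTODOMAIN = Region(28, 955)


def classify_variant(wt_aa: str, alt: str) -> str:
    """Classify a single residue change.

    Returns one of ``"synonymous"``, ``"missense"``, ``"nonsense"`` or
    ``"wild_type"``.  ``alt`` may be an amino acid, ``"*"`` (stop) or ``"="``
    (explicit synonymous marker); an alt equal to the wild-type residue is
    synonymous at the protein level.
    """
    if wt_aa not in AMINO_ACIDS and wt_aa != SYNONYMOUS:
        raise ValueError(f"unknown wild-type residue {wt_aa!r}")
    if wt_aa == SYNONYMOUS:  # unmutated barcode rows use '=' in both columns
        return "wild_type"
    if alt == STOP:
        return "nonsense"
    if alt == SYNONYMOUS or alt == wt_aa:
        return "synonymous"
    if alt not in AMINO_ACIDS:
        raise ValueError(f"unknown alternate residue {alt!r}")
    return "missense"


@dataclass(frozen=True, order=True)
class VariantSpec:
    """One amino-acid-level change in preproprotein coordinates."""

    position: int
    wt_aa: str
    alt: str

    def __post_init__(self) -> None:
        classify_variant(self.wt_aa, self.alt)  # validates symbols

    @property
    def klass(self) -> str:
        return classify_variant(self.wt_aa, self.alt)

    @property
    def id(self) -> str:
        """Compact identifier, e.g. ``G333Q``, ``W516*``, ``A119=``."""
        return f"{self.wt_aa}{self.position}{self.alt}"


def region_codon_count(region: Region) -> int:
    """Number of codons (residues) spanned by ``region``."""
    return len(region)


def enumerate_possible_variants(
    region: Region,
    wt_sequence: str,
    include_nonsense: bool = True,
) -> list[VariantSpec]:
    """All single missense (and optionally stop) variants over ``region``.

    ``wt_sequence`` supplies the wild-type residue at each position of the
    region (length must equal the region length).  Per position there are 19
    missense outcomes plus one stop, i.e. 20 x region length in total —
    18,560 over the 928-codon ectodomain.
    """
    if len(wt_sequence) != len(region):
        raise ValueError(
            f"wt_sequence length {len(wt_sequence)} != region length {len(region)}"
        )
    out: list[VariantSpec] = []
    for pos, wt in zip(region.positions, wt_sequence):
        for aa in AMINO_ACIDS:
            if aa != wt:
                out.append(VariantSpec(pos, wt, aa))
        if include_nonsense:
            out.append(VariantSpec(pos, wt, STOP))
    return out


def nns_codon_outcomes() -> dict[str, str]:
    """Translation of every NNS codon (third base G or C) under the standard code.

    The 32-codon domain covers all 20 amino acids and exactly one stop codon
    (TAG); TAA and TGA end in A and are outside the NNS repertoire.
    """
    table = standard_dna_table.forward_table
    out: dict[str, str] = {}
    for b1, b2, b3 in itertools.product("ACGT", "ACGT", "GC"):
        codon = b1 + b2 + b3
        out[codon] = table.get(codon, STOP)
    return out


def plan_mutagenesis_pools(region: Region, block_size: int = 20) -> list[Region]:
    """Partition ``region`` into sequential blocks of ``block_size`` codons.

    Mutagenesis oligos are synthesised in pools each covering a block of
    sequential codons (47 pools of 20 over the 928-codon ectodomain); the last
    block may be shorter.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    blocks = []
    start = region.start_pos
    while start <= region.end_pos:
        blocks.append(Region(start, min(start + block_size - 1, region.end_pos)))
        start += block_size
    return blocks


def _validate_map(bvmap: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _MAP_COLUMNS if c not in bvmap.columns]
    if missing:
        raise ValueError(f"barcode-variant map missing columns {missing}")
    lengths = bvmap["barcode"].str.len().unique()
    if len(lengths) > 1:
        raise ValueError(f"barcodes of unequal length: {sorted(lengths)}")
    bad = bvmap["barcode"].str.contains(r"[^ACGT]", regex=True)
    if bad.any():
        raise ValueError("barcodes contain characters outside {A,C,G,T}")
    return bvmap


def variant_ids(bvmap: pd.DataFrame) -> pd.Series:
    """Per-row variant identifier; unmutated rows collapse to ``"WT"``."""
    ids = (
        bvmap["wt_aa"].astype(str)
        + bvmap["position"].astype(int).astype(str)
        + bvmap["alt_aa"].astype(str)
    )
    return ids.mask(bvmap["wt_aa"].eq(SYNONYMOUS), "WT")


def filter_barcode_collisions(
    bvmap: pd.DataFrame, max_mismatch: int = 2
) -> pd.DataFrame:
    """Drop barcodes that nearly collide with a differently-assigned barcode.

    Barcode pairs within ``max_mismatch`` Hamming distance but linked to
    different variant calls are conflicts: the member with the higher long-read
    (CCS) support is retained and the lower-support member dropped.  When
    support is tied, both are dropped (conservative).  Pairs assigned to the
    same variant are never touched.  The operation is idempotent and never
    adds rows.
    """
    _validate_map(bvmap)
    n = len(bvmap)
    if n <= 1:
        return bvmap.copy()
    codes = np.frombuffer(
        "".join(bvmap["barcode"]).encode("ascii"), dtype=np.uint8
    ).reshape(n, -1)
    support = bvmap["support_reads"].to_numpy()
    ids = variant_ids(bvmap).to_numpy()
    drop = np.zeros(n, dtype=bool)
    # pairwise Hamming in row chunks to bound memory on large maps
    chunk = max(1, 2_000_000 // max(n, 1))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        dist = (codes[lo:hi, None, :] != codes[None, :, :]).sum(axis=2)
        near = dist <= max_mismatch
        near[np.arange(lo, hi) - lo, np.arange(lo, hi)] = False
        conflict = near & (ids[lo:hi, None] != ids[None, :])
        loses = conflict & (support[lo:hi, None] <= support[None, :])
        drop[lo:hi] |= loses.any(axis=1)
    return bvmap.loc[~drop].copy()


def read_barcode_variant_map(path) -> pd.DataFrame:
    """Read a barcode-variant map TSV (columns barcode, position, wt_aa,
    alt_aa, support_reads)."""
    bvmap = pd.read_csv(
        path,
        sep="\t",
        dtype={"barcode": str, "wt_aa": str, "alt_aa": str},
    )
    bvmap["position"] = bvmap["position"].astype(int)
    bvmap["support_reads"] = bvmap["support_reads"].astype(int)
    return _validate_map(bvmap)


def write_barcode_variant_map(bvmap: pd.DataFrame, path) -> None:
    _validate_map(bvmap)
    bvmap.to_csv(path, sep="\t", index=False, columns=_MAP_COLUMNS)
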