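"""Somatic variants, VAF-based clonality partitioning, and 96-channel catalogs.

This module turns somatic SNV calls plus an indexed reference genome into
:class:`MutationCatalog96` objects — the container every downstream signature
fit consumes — and splits a variant list into clonal and subclonal strata from
variant allele frequencies alone (no copy-number adjustment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .channels import (
    BASES,
    CHANNEL_LABELS,
    N_CHANNELS,
    TrinucleotideChannel,
)

logger = logging.getLogger(__name__)


class ReferenceMismatchError(ValueError):
    """Reference genome base does not match a variant's reference allele."""


class AmbiguousContextError(ValueError):
    """Trinucleotide context contains an ambiguous (N) base."""


@dataclass(frozen=True)
class SomaticVariant:
    """A somatic single-nucleotide variant with read support.

    ``vaf`` defaults to ``alt_depth / total_depth`` when not supplied
    explicitly (it may be supplied, e.g. for calls quoted without depths).
    """

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    total_depth: int = 0
    alt_depth: int = 0
    vaf: float | None = None

    def __post_init__(self):
        ref, alt = self.ref_allele.upper(), self.alt_allele.upper()
        object.__setattr__(self, "ref_allele", ref)
        object.__setattr__(self, "alt_allele", alt)
        if self.is_snv:
            if ref == alt:
                raise ValueError(f"{self.chrom}:{self.pos} ref == alt ({ref})")
        if self.alt_depth > self.total_depth:
            raise ValueError(
                f"{self.chrom}:{self.pos} alt_depth {self.alt_depth} > total_depth {self.total_depth}"
            )
        if self.vaf is None:
            vaf = self.alt_depth / self.total_depth if self.total_depth > 0 else float("nan")
            object.__setattr__(self, "vaf", vaf)
        elif not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"{self.chrom}:{self.pos} VAF {self.vaf} outside [0, 1]")

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref_allele) == 1
            and len(self.alt_allele) == 1
            and self.ref_allele in BASES
            and self.alt_allele in BASES
        )

    @property
    def key(self) -> tuple:
        """Identity used for set comparisons: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


def _fetch(reference, chrom: str, start0: int, end0: int) -> str:
    """Fetch reference sequence [start0, end0) from a pyfaidx.Fasta, a pysam
    FastaFile, or a plain mapping of contig name -> sequence string."""
    if isinstance(reference, Mapping):
        return str(reference[chrom][start0:end0]).upper()
    if hasattr(reference, "fetch"):  # pysam.FastaFile
        return reference.fetch(chrom, start0, end0).upper()
    return str(reference[chrom][start0:end0]).upper()  # pyfaidx.Fasta


def extract_context(variant: SomaticVariant, reference) -> TrinucleotideChannel:
    """Pyrimidine-normalized trinucleotide channel of a variant.

    Raises :class:`ReferenceMismatchError` if the reference base at the
    variant position disagrees with ``ref_allele`` (case-insensitive) and
    :class:`AmbiguousContextError` if a flanking base is N.
    """
    if not variant.is_snv:
        raise ValueError(f"{variant.chrom}:{variant.pos} is not an SNV")
    tri = _fetch(reference, variant.chrom, variant.pos - 2, variant.pos + 1)
    if len(tri) != 3:
        raise ValueError(f"{variant.chrom}:{variant.pos} context out of reference bounds")
    if tri[1] != variant.ref_allele:
        raise ReferenceMismatchError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: "
            f"reference has {tri[1]!r}, variant claims {variant.ref_allele!r}"
        )
    if "N" in tri:
        raise AmbiguousContextError(
            f"ambiguous context {tri!r} at {variant.chrom}:{variant.pos}"
        )
    return TrinucleotideChannel.from_change(variant.ref_allele, variant.alt_allele, tri[0], tri[2])


class MutationCatalog96:
    """Counts over the 96 substitution channels for one sample/partition."""

    def __init__(self, counts=None, label: str = ""):
        if counts is None:
            counts = np.zeros(N_CHANNELS)
        counts = np.asarray(counts, dtype=float)
        if counts.shape != (N_CHANNELS,):
            raise ValueError(f"expected {N_CHANNELS} channel counts, got shape {counts.shape}")
        if (counts < 0).any():
            raise ValueError("channel counts must be nonnegative")
        self.counts = counts
        self.label = label

    @property
    def n_total(self) -> float:
        return float(self.counts.sum())

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CHANNEL_LABELS), name=self.label or "count")

    def to_tsv(self, path) -> None:
        """Write a 97-line TSV: header plus one (channel, count) row per channel."""
        df = self.to_series().rename("count").rename_axis("channel").reset_index()
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, label: str | None = None) -> "MutationCatalog96":
        df = pd.read_csv(path, sep="\t")
        ser = df.set_index(df.columns[0])[df.columns[1]]
        counts = ser.reindex(list(CHANNEL_LABELS))
        if counts.isna().any():
            missing = [l for l in CHANNEL_LABELS if l not in ser.index]
            raise ValueError(f"catalog TSV missing channels, e.g. {missing[:3]}")
        return cls(counts.to_numpy(), label=label if label is not None else Path(path).stem)

    def __add__(self, other: "MutationCatalog96") -> "MutationCatalog96":
        return MutationCatalog96(self.counts + other.counts, label=self.label)

    def __repr__(self) -> str:
        return f"MutationCatalog96(label={self.label!r}, n_total={self.n_total:g})"

    def plot(self, ax=None):
        """Standard 96-channel profile bar plot, colored by substitution class."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(12, 3))
        palette = ["#03bcee", "#010101", "#e32926", "#cac9c9", "#a1ce63", "#ebc6c4"]
        colors = [palette[i // 16] for i in range(N_CHANNELS)]
        ax.bar(range(N_CHANNELS), self.counts, color=colors, width=0.8)
        ax.set_xticks(range(0, N_CHANNELS, 16))
        ax.set_xticklabels([f"{s}" for s in ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")])
        ax.set_ylabel("mutations")
        ax.set_title(self.label)
        return ax


def build_catalog(
    variants: Iterable[SomaticVariant], reference, label: str = ""
) -> MutationCatalog96:
    """Build a 96-channel catalog from SNVs; non-SNV records and variants with
    ambiguous context are skipped with a logged count. Reference-allele
    mismatches raise (they indicate a data-integrity problem, not noise)."""
    counts = np.zeros(N_CHANNELS)
    n_skipped_non_snv = 0
    n_skipped_ambiguous = 0
    for v in variants:
        if not v.is_snv:
            n_skipped_non_snv += 1
            continue
        try:
            ch = extract_context(v, reference)
        except AmbiguousContextError:
            n_skipped_ambiguous += 1
            continue
        counts[ch.index] += 1
    if n_skipped_non_snv or n_skipped_ambiguous:
        logger.info(
            "build_catalog(%s): skipped %d non-SNV and %d ambiguous-context records",
            label, n_skipped_non_snv, n_skipped_ambiguous,
        )
    return MutationCatalog96(counts, label=label)


@dataclass
class ClonalityPartition:
    """Deterministic clonal/subclonal split of a variant list by VAF."""

    clonal: list
    subclonal: list
    excluded: list
    purity: float
    expected_clonal_vaf: float
    method_parameters: dict = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return len(self.clonal) + len(self.subclonal) + len(self.excluded)


def partition_clonality(
    variants: Sequence[SomaticVariant],
    purity: float | None = None,
    alpha: float = 0.01,
) -> ClonalityPartition:
    """Split variants into clonal and subclonal sets by VAF.

    A diploid heterozygous clonal mutation in a tumor of the given purity is
    expected at VAF = purity / 2.  A variant is called clonal when a two-sided
    binomial test of ``alt_depth`` out of ``total_depth`` against that
    expectation is *not* rejected at ``alpha``, or when its VAF is at or above
    the expectation; otherwise subclonal.  Zero-depth variants are excluded
    with a logged count.

    When ``purity`` is None it is estimated as twice the median VAF, capped at
    1.  This VAF-only rule is a parameterized stand-in for supplementary-level
    clonality calling; copy-number-aware cancer-cell fractions are out of scope.
    """
    usable = [v for v in variants if v.total_depth > 0]
    excluded = [v for v in variants if v.total_depth <= 0]
    if excluded:
        logger.info("partition_clonality: excluded %d zero-depth variants", len(excluded))
    if purity is None:
        if not usable:
            raise ValueError("cannot estimate purity from an empty variant list")
        purity = min(1.0, 2.0 * float(np.median([v.vaf for v in usable])))
    if not (0.0 < purity <= 1.0):
        raise ValueError(f"purity {purity} outside (0, 1]")
    expected = purity / 2.0

    clonal, subclonal = [], []
    for v in usable:
        if v.vaf >= expected:
            clonal.append(v)
            continue
        p = stats.binomtest(v.alt_depth, v.total_depth, expected).pvalue
        (clonal if p > alpha else subclonal).append(v)
    return ClonalityPartition(
        clonal=clonal,
        subclonal=subclonal,
        excluded=excluded,
        purity=purity,
        expected_clonal_vaf=expected,
        method_parameters={
            "rule": "binomial-stand-in",
            "alpha": alpha,
            "test": "two-sided binomial vs purity/2",
        },
    )


def read_vcf(
    path,
    sample: str | None = None,
    ad_field: str = "AD",
    dp_field: str = "DP",
) -> list[SomaticVariant]:
    """Read SNVs with depths from a VCF 4.x file (plain or bgzipped).

    Depths come from the named FORMAT fields of ``sample`` (first sample by
    default): ``ad_field`` as (ref, alt, ...) allele depths and ``dp_field``
    as total depth (fallback: sum of AD).  Multiallelic records are
    decomposed into one variant per alternate allele.
    """
    import pysam

    variants: list[SomaticVariant] = []
    with pysam.VariantFile(str(path)) as vf:
        if sample is None and len(vf.header.samples) > 0:
            sample = vf.header.samples[0]
        for rec in vf:
            if not rec.alts:
                continue
            fmt = rec.samples[sample] if sample is not None else None
            ad = fmt.get(ad_field) if fmt is not None else None
            dp = fmt.get(dp_field) if fmt is not None else None
            for i, alt in enumerate(rec.alts):
                alt_depth = int(ad[i + 1]) if ad is not None and ad[i + 1] is not None else 0
                if dp is not None:
                    total = int(dp)
                elif ad is not None:
                    total = int(sum(x for x in ad if x is not None))
                else:
                    total = 0
                variants.append(
                    SomaticVariant(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        total_depth=total,
                        alt_depth=alt_depth,
                    )
                )
    return variants


def load_reference(path):
    """Open an indexed FASTA (creates the .fai on first use)."""
    import pyfaidx

    return pyfaidx.Fasta(str(path), sequence_always_upper=True)
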