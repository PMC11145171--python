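"""Genome-wide mutation burden extrapolated from a duplex-sequencing panel.

A targeted duplex panel (tens of kb, trinucleotide composition similar to the
whole genome) observes somatic mutations at very low VAF in bulk normal
tissue.  Each duplex call is a unique molecular event in one sequenced
molecule, so the per-channel mutation *rate* is calls divided by the duplex
bases interrogated at matching trinucleotide contexts:

    r_c = m_c / D_c
    g_c = r_c * G_c

where ``D_c`` sums per-position duplex depth over panel positions whose
reference trinucleotide matches channel *c*'s context and ``G_c`` is the
number of occurrences of that trinucleotide in the genome of a cell (haploid
table doubled for the diploid default).  Channel-level correction removes the
residual composition bias of a panel that is only *similar* to the genome.
Decomposing the genome-scaled channel counts ``{g_c}`` over a signature set
yields per-signature per-genome burdens; dividing by exposure days gives
per-day mutation rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import MutationCatalog96, SomaticVariant, _fetch, extract_context
from .channels import (
    CHANNEL_TO_TRINUC32,
    N_CHANNELS,
    N_CONTEXTS,
    TRINUCLEOTIDES_32,
    trinucleotide32_index,
)
from .signatures import (
    AGE_RELATED_SIGNATURES,
    PLATINUM_SIGNATURES,
    ExposureVector,
    SignatureSet,
    _fit_batch,
    fit_exposures,
)

#: default diploid genome size (autosomes + X, bp), sex-agnostic
DEFAULT_GENOME_SIZE = 6.2e9

DAYS_PER_YEAR = 365.25


def trinucleotide_composition(reference, contigs=None) -> np.ndarray:
    """Counts of the 32 pyrimidine-centered trinucleotides over all interior
    positions of the given contigs (all contigs by default)."""
    comp = np.zeros(N_CONTEXTS)
    if contigs is None:
        contigs = list(reference.keys()) if isinstance(reference, Mapping) else [
            k for k in reference.keys()
        ]
    for chrom in contigs:
        seq = _fetch(reference, chrom, 0, int(1e12))
        comp += _composition_of_sequence(seq)
    return comp


_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

_TRI64_TO_32 = np.full(64, -1, dtype=np.int64)
for _c5 in range(4):
    for _mid in range(4):
        for _c3 in range(4):
            _tri = "ACGT"[_c5] + "ACGT"[_mid] + "ACGT"[_c3]
            _TRI64_TO_32[16 * _c5 + 4 * _mid + _c3] = trinucleotide32_index(_tri)


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


def _trinuc32_per_position(seq: str) -> np.ndarray:
    """Per-position pyrimidine-normalized trinucleotide index (-1 at edges or
    where any base of the context is ambiguous)."""
    code = _encode(seq)
    out = np.full(code.shape, -1, dtype=np.int64)
    if code.size < 3:
        return out
    c5, mid, c3 = code[:-2], code[1:-1], code[2:]
    ok = (c5 >= 0) & (mid >= 0) & (c3 >= 0)
    tri64 = 16 * c5 + 4 * mid + c3
    out[1:-1][ok] = _TRI64_TO_32[tri64[ok]]
    return out


def _composition_of_sequence(seq: str) -> np.ndarray:
    tri = _trinuc32_per_position(seq)
    return np.bincount(tri[tri >= 0], minlength=N_CONTEXTS).astype(float)


class CallOutsidePanelError(ValueError):
    """A duplex call lies outside every panel interval."""


class DepthInconsistencyError(ValueError):
    """Calls observed in a channel whose context has zero duplex depth."""


@dataclass
class DuplexPanel:
    """Panel intervals with per-position duplex depth and compositions.

    ``intervals`` are half-open 0-based (chrom, start, end) triples;
    ``positions`` / ``depth`` hold every covered position (1-based) and its
    duplex-consensus depth; ``context32`` the pyrimidine-normalized
    trinucleotide index of each position (-1 where ambiguous).
    """

    intervals: list
    positions: list  # list of (chrom, pos1)
    depth: np.ndarray
    context32: np.ndarray
    genome_composition: np.ndarray  # 32 counts (haploid occurrence counts or fractions)

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        self.context32 = np.asarray(self.context32, dtype=np.int64)
        if (self.depth < 0).any():
            raise ValueError("negative duplex depth")
        if len(self.positions) != self.depth.shape[0] != self.context32.shape[0]:
            raise ValueError("positions, depth and context arrays misaligned")

    @property
    def panel_size(self) -> int:
        return int(sum(end - start for _, start, end in self.intervals))

    @property
    def effective_duplex_bases(self) -> float:
        return float(self.depth.sum())

    @property
    def panel_composition(self) -> np.ndarray:
        """Depth-weighted duplex bases per trinucleotide context (32,)."""
        ok = self.context32 >= 0
        return np.bincount(
            self.context32[ok], weights=self.depth[ok], minlength=N_CONTEXTS
        )

    def contains(self, chrom: str, pos1: int) -> bool:
        return any(c == chrom and start < pos1 <= end for c, start, end in self.intervals)

    @classmethod
    def from_reference(
        cls,
        intervals: Sequence[tuple],
        reference,
        depth,
        genome_composition: np.ndarray | None = None,
    ) -> "DuplexPanel":
        """Build a panel from BED-style intervals, an indexed reference and
        per-position depth (scalar, or mapping (chrom, pos1) -> depth).
        ``genome_composition`` defaults to the composition of the whole
        reference (use the real genome's 32-mer table, or a rescaled
        representative composition, when the reference is a subsample)."""
        positions, ctx, dep = [], [], []
        for chrom, start, end in intervals:
            seq = _fetch(reference, chrom, max(start - 1, 0), end + 1)
            offset = 1 if start > 0 else 0
            tri = _trinuc32_per_position(seq)
            for i, pos0 in enumerate(range(start, end)):
                pos1 = pos0 + 1
                positions.append((chrom, pos1))
                ctx.append(tri[i + offset])
                if np.isscalar(depth):
                    dep.append(float(depth))
                else:
                    dep.append(float(depth.get((chrom, pos1), 0.0)))
        if genome_composition is None:
            genome_composition = trinucleotide_composition(reference)
        return cls(
            intervals=list(intervals),
            positions=positions,
            depth=np.array(dep),
            context32=np.array(ctx, dtype=np.int64),
            genome_composition=np.asarray(genome_composition, dtype=float),
        )

    @classmethod
    def from_files(cls, bed_path, depth_tsv, reference, genome_composition=None) -> "DuplexPanel":
        """Read intervals from a BED file and per-position duplex depth from a
        TSV with columns (chrom, pos, duplex_depth); pos is 1-based."""
        intervals = []
        with open(bed_path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = line.split()[:3]
                intervals.append((chrom, int(start), int(end)))
        df = pd.read_csv(depth_tsv, sep="\t")
        depth = {
            (str(r.iloc[0]), int(r.iloc[1])): float(r.iloc[2]) for _, r in df.iterrows()
        }
        return cls.from_reference(intervals, reference, depth, genome_composition)


@dataclass
class DuplexCallSet:
    """Duplex-consensus mutation calls restricted to a panel.

    Each call is a unique molecular event: a variant supported by multiple
    duplex families at one site counts once, and sites whose VAF against the
    local duplex depth exceeds ``vaf_ceiling`` are excluded as clonal or
    germline leakage.
    """

    calls: list
    sample_label: str = ""
    vaf_ceiling: float = 0.05

    def usable_calls(self, panel: DuplexPanel) -> list:
        outside = [v for v in self.calls if not panel.contains(v.chrom, v.pos)]
        if outside:
            locs = ", ".join(f"{v.chrom}:{v.pos}" for v in outside[:5])
            raise CallOutsidePanelError(
                f"{len(outside)} duplex calls outside the panel (e.g. {locs})"
            )
        depth_at = dict(zip(panel.positions, panel.depth))
        seen: set = set()
        usable = []
        for v in self.calls:
            if v.key in seen:  # one molecular event per unique variant
                continue
            seen.add(v.key)
            d = depth_at.get((v.chrom, v.pos), 0.0)
            if d > 0 and v.alt_depth / d > self.vaf_ceiling:
                continue
            usable.append(v)
        return usable


def panel_profile(calls: DuplexCallSet, panel: DuplexPanel, reference) -> MutationCatalog96:
    """96-channel catalog of the panel's duplex calls (one count per call)."""
    counts = np.zeros(N_CHANNELS)
    for v in calls.usable_calls(panel):
        counts[extract_context(v, reference).index] += 1
    return MutationCatalog96(counts, label=calls.sample_label)


@dataclass
class BurdenEstimate:
    """Per-cell genome-wide mutation burden extrapolated from a panel."""

    mutations_per_genome_total: float
    mutations_per_genome_by_signature: dict
    interval: tuple
    coverage: float
    effective_duplex_bases: float
    genome_size_used: float
    by_signature_intervals: dict = field(default_factory=dict)
    n_calls: int = 0
    sample_label: str = ""

    def group_total(self, group) -> float:
        return float(sum(self.mutations_per_genome_by_signature.get(n, 0.0) for n in group))

    def group_interval(self, group) -> tuple:
        lows = [self.by_signature_intervals.get(n, (0.0, 0.0)) for n in group if n in self.by_signature_intervals]
        if not lows:
            return (0.0, 0.0)
        return (sum(l for l, _ in lows), sum(h for _, h in lows))

    def to_dict(self) -> dict:
        return {
            "sample": self.sample_label,
            "mutations_per_genome_total": self.mutations_per_genome_total,
            "mutations_per_genome_by_signature": dict(self.mutations_per_genome_by_signature),
            "interval_low": self.interval[0],
            "interval_high": self.interval[1],
            "coverage": self.coverage,
            "effective_duplex_bases": self.effective_duplex_bases,
            "genome_size_used": self.genome_size_used,
            "n_calls": self.n_calls,
        }

    def summary(self) -> str:
        lines = [
            "Genome-wide burden from duplex panel",
            "=" * 44,
            f"sample:                {self.sample_label or '<unnamed>'}",
            f"panel calls:           {self.n_calls}",
            f"effective duplex bases: {self.effective_duplex_bases:.3g}",
            f"genome size used:      {self.genome_size_used:.3g} bp",
            f"total per genome:      {self.mutations_per_genome_total:.1f} "
            f"[{self.interval[0]:.1f}, {self.interval[1]:.1f}] ({self.coverage:.0%})",
            "-" * 44,
        ]
        for name, val in self.mutations_per_genome_by_signature.items():
            lo, hi = self.by_signature_intervals.get(name, (float("nan"), float("nan")))
            lines.append(f"{name:<12}{val:>10.1f}  [{lo:.1f}, {hi:.1f}]")
        return "\n".join(lines)


class DuplexBurdenModel:
    """Model object tying panel calls, panel design and signatures together.

    ``fit()`` performs the channel-wise extrapolation, the signature
    decomposition of the genome-scaled counts, and a parametric bootstrap
    (Poisson uncertainty on the per-channel call counts) for the interval.
    """

    def __init__(
        self,
        calls: DuplexCallSet,
        panel: DuplexPanel,
        signatures: SignatureSet,
        reference,
        genome_size: float = DEFAULT_GENOME_SIZE,
    ):
        self.calls = calls
        self.panel = panel
        self.signatures = signatures
        self.reference = reference
        self.genome_size = float(genome_size)

    def _channel_tables(self):
        """(m_c, D_c, G_c) per channel."""
        catalog = panel_profile(self.calls, self.panel, self.reference)
        m = catalog.counts
        D_ctx = self.panel.panel_composition
        comp = self.panel.genome_composition
        G_ctx = comp / comp.sum() * self.genome_size
        idx = np.asarray(CHANNEL_TO_TRINUC32)
        return m, D_ctx[idx], G_ctx[idx]

    def fit(self, coverage: float = 0.95, n_boot: int = 1000, seed=None) -> BurdenEstimate:
        if self.panel.effective_duplex_bases <= 0:
            raise ValueError("panel has zero effective duplex bases")
        m, D, G = self._channel_tables()
        if ((D == 0) & (m > 0)).any():
            bad = [c for c in range(N_CHANNELS) if D[c] == 0 and m[c] > 0]
            raise DepthInconsistencyError(
                f"calls observed in channels with zero matching duplex depth: {bad}"
            )
        scale = np.where(D > 0, G / np.maximum(D, 1.0), 0.0)
        g = m * scale
        exposures = _decompose(g, self.signatures)
        by_sig = dict(zip(self.signatures.names, exposures))
        total = float(sum(by_sig.values()))

        rng = np.random.default_rng(seed)
        # parametric bootstrap: panel-scale expected calls from the fitted
        # model (smooths zero-count channels), Poisson-resampled
        mu_g = exposures @ self.signatures.matrix
        mu_m = np.where(scale > 0, mu_g / np.where(scale > 0, scale, 1.0), 0.0)
        if mu_m.sum() > 0:
            Mb = rng.poisson(mu_m, size=(n_boot, N_CHANNELS)).astype(float)
            Gb = Mb * scale
            Eb = _fit_batch(
                Gb, self.signatures.matrix, tol=1e-6, omega=1.8, init=exposures
            )
            totals = Eb.sum(axis=1)
            lo_q, hi_q = (1 - coverage) / 2, 1 - (1 - coverage) / 2
            interval = (float(np.quantile(totals, lo_q)), float(np.quantile(totals, hi_q)))
            sig_iv = {
                name: (float(np.quantile(Eb[:, i], lo_q)), float(np.quantile(Eb[:, i], hi_q)))
                for i, name in enumerate(self.signatures.names)
            }
        else:
            # zero calls: exact Poisson zero-count upper bound per signature
            tail = -np.log((1 - coverage) / 2)
            sig_iv = {}
            for i, name in enumerate(self.signatures.names):
                lam_per_burden = float((self.signatures.matrix[i] / np.where(scale > 0, scale, np.inf)).sum())
                upper = tail / lam_per_burden if lam_per_burden > 0 else float("inf")
                sig_iv[name] = (0.0, upper)
            interval = (0.0, max(hi for _, hi in sig_iv.values()))

        interval = (min(interval[0], total), max(interval[1], total))
        return BurdenEstimate(
            mutations_per_genome_total=total,
            mutations_per_genome_by_signature=by_sig,
            interval=interval,
            coverage=coverage,
            effective_duplex_bases=self.panel.effective_duplex_bases,
            genome_size_used=self.genome_size,
            by_signature_intervals=sig_iv,
            n_calls=int(m.sum()),
            sample_label=self.calls.sample_label,
        )


def _decompose(g: np.ndarray, signatures: SignatureSet) -> np.ndarray:
    cat = MutationCatalog96(np.maximum(g, 0.0))
    if cat.n_total == 0:
        return np.zeros(len(signatures))
    return fit_exposures(cat, signatures).activities


def estimate_genomewide_burden(
    calls: DuplexCallSet,
    panel: DuplexPanel,
    signatures: SignatureSet,
    reference,
    genome_size: float = DEFAULT_GENOME_SIZE,
    coverage: float = 0.95,
    n_boot: int = 1000,
    seed=None,
) -> BurdenEstimate:
    """Functional wrapper over :class:`DuplexBurdenModel`."""
    return DuplexBurdenModel(calls, panel, signatures, reference, genome_size).fit(
        coverage=coverage, n_boot=n_boot, seed=seed
    )


@dataclass
class ExposureHistory:
    """Treatment and age bookkeeping, in days (365.25 days/year)."""

    treatment_days: int
    age_at_sampling_days: float
    age_at_treatment_start_days: float | None = None

    def __post_init__(self):
        if self.treatment_days < 1:
            raise ValueError("treatment_days must be >= 1")
        if (
            self.age_at_treatment_start_days is not None
            and self.age_at_treatment_start_days > self.age_at_sampling_days
        ):
            raise ValueError("treatment start after sampling age")

    @classmethod
    def from_years(cls, treatment_days: int, age_years: float, age_at_treatment_start_years=None):
        return cls(
            treatment_days=treatment_days,
            age_at_sampling_days=age_years * DAYS_PER_YEAR,
            age_at_treatment_start_days=(
                None if age_at_treatment_start_years is None
                else age_at_treatment_start_years * DAYS_PER_YEAR
            ),
        )


def per_day_rates(
    burden_or_exposures: BurdenEstimate | ExposureVector,
    history: ExposureHistory,
    platinum_signatures=PLATINUM_SIGNATURES,
    age_related_signatures=AGE_RELATED_SIGNATURES,
) -> dict:
    """Platinum mutations per treatment day and age-related mutations per day
    of life, from either a genome-wide burden estimate or fitted activities."""
    if history.age_at_sampling_days < 1:
        raise ValueError("age at sampling must be at least 1 day")
    src = burden_or_exposures
    platinum = src.group_total(platinum_signatures)
    age_related = src.group_total(age_related_signatures)
    return {
        "platinum_per_treatment_day": platinum / history.treatment_days,
        "age_related_per_life_day": age_related / history.age_at_sampling_days,
    }
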