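"""Synthetic data generation for every pipeline input.

Generates a random reference genome, signature-mixture mutation catalogs,
paired-tumor VCFs with clonal/subclonal VAF structure and planted
early-embryonic shared mutations, and duplex-panel designs with calls at a
configured per-genome burden — each with a machine-readable truth table, so
every downstream operation can be scored without access to patient data.

Randomness: a single top-level seed fans out to per-stage seeds through
:class:`numpy.random.SeedSequence` spawning, so stages are independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .catalog import MutationCatalog96, SomaticVariant
from .channels import (
    CHANNELS,
    CHANNEL_LABELS,
    CHANNEL_TO_TRINUC32,
    COMPLEMENT,
    N_CHANNELS,
    PYRIMIDINES,
)
from .duplex import DuplexCallSet, DuplexPanel, _trinuc32_per_position
from .signatures import SignatureSet, load_bundled_signatures


@dataclass
class SimulationConfig:
    """All knobs of the generators, serializable to/from YAML.

    Defaults mirror the study conditions the pipeline targets: ~120X bulk
    depth, tumor purity 0.8, tAML-scale clonal burdens, a 48 kb / 20-interval
    duplex panel at ~20,000X.
    """

    seed: int = 0
    signature_mixture: dict = field(
        default_factory=lambda: {"SBS5": 0.6, "SBS1": 0.2, "SBS40": 0.2}
    )
    n_mutations: int = 2000
    purity: float = 0.8
    depth: int = 120
    subclonal_fraction: float = 0.3
    subclonal_cell_fraction: tuple = (0.05, 0.2)
    shared_early_mutations: int = 0
    n_contigs: int = 2
    contig_length: int = 1_000_000
    gc_fraction: float = 0.41
    panel_size: int = 48_000
    n_panel_intervals: int = 20
    mean_duplex_depth: float = 20_000.0
    duplex_burden_per_genome: dict = field(default_factory=dict)
    genome_size: float = 6.2e9

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)

    def spawn(self, n: int):
        return np.random.SeedSequence(self.seed).spawn(n)


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------

def simulate_reference(
    n_contigs: int = 2,
    contig_length: int = 1_000_000,
    gc_fraction: float = 0.41,
    seed=0,
) -> dict:
    """Random reference sequences at the stated GC content, as a mapping
    contig name -> sequence string (deterministic per seed)."""
    if contig_length < 1000:
        raise ValueError("contig_length must be >= 1000")
    rng = np.random.default_rng(seed)
    p = np.array([
        (1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2,
    ])
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return {
        f"chr{i + 1}": bases[rng.choice(4, size=contig_length, p=p)].tobytes().decode()
        for i in range(n_contigs)
    }


def write_reference(reference: Mapping[str, str], path) -> Path:
    """Write a FASTA (60-column) and build its .fai index."""
    import pyfaidx

    path = Path(path)
    with path.open("w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    pyfaidx.Faidx(str(path))
    return path


# ---------------------------------------------------------------------------
# Catalogs from signature mixtures
# ---------------------------------------------------------------------------

def _mixture_matrix(mixture: Mapping[str, float], signatures: SignatureSet | None):
    if signatures is None:
        signatures = load_bundled_signatures()
    names = list(mixture)
    fracs = np.array([mixture[n] for n in names], dtype=float)
    if (fracs < 0).any() or abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError(f"mixture fractions must be nonnegative and sum to 1: {mixture}")
    P = signatures.subset(names).matrix
    return names, fracs, P


def simulate_catalog(
    mixture: Mapping[str, float],
    n_mutations: int,
    signatures: SignatureSet | None = None,
    seed=None,
    label: str = "",
):
    """One multinomial catalog drawn from a signature mixture.

    Returns ``(catalog, truth)`` where ``truth`` maps signature name to the
    realized number of mutations it generated.
    """
    counts, per_sig = simulate_catalogs(mixture, n_mutations, 1, signatures=signatures, seed=seed)
    names = list(mixture)
    truth = {n: int(per_sig[0, i]) for i, n in enumerate(names)}
    return MutationCatalog96(counts[0], label=label), truth


def simulate_catalogs(
    mixture: Mapping[str, float],
    n_mutations: int,
    n_catalogs: int,
    signatures: SignatureSet | None = None,
    seed=None,
):
    """Batch of multinomial catalogs from a signature mixture.

    Returns ``(counts, per_signature)`` with shapes (B, 96) and (B, S):
    mutation totals are first split multinomially across signatures, then each
    signature's share is drawn from its channel distribution, so the truth
    table carries the realized per-signature counts.
    """
    rng = np.random.default_rng(seed)
    names, fracs, P = _mixture_matrix(mixture, signatures)
    per_sig = rng.multinomial(n_mutations, fracs, size=n_catalogs)  # (B, S)
    counts = np.zeros((n_catalogs, N_CHANNELS))
    for s in range(len(names)):
        counts += rng.multinomial(per_sig[:, s], P[s])
    return counts, per_sig


# ---------------------------------------------------------------------------
# Paired tumors with shared early-embryonic mutations
# ---------------------------------------------------------------------------

def _positions_by_context(reference: Mapping[str, str]):
    """For each of the 32 contexts, the (chrom, pos1) sites carrying it."""
    sites = [[] for _ in range(32)]
    for chrom, seq in reference.items():
        tri = _trinuc32_per_position(seq)
        for ctx in range(32):
            for pos0 in np.flatnonzero(tri == ctx):
                sites[ctx].append((chrom, int(pos0) + 1))
    return sites


def _variant_at(reference, chrom, pos1, channel, rng, depth, vaf_p):
    """Materialize a variant of the given channel at a context-matched site,
    with binomial read support around ``vaf_p``."""
    ref_base = reference[chrom][pos1 - 1].upper()
    if ref_base in PYRIMIDINES:
        alt = channel.alt_base
    else:  # site carries the purine strand of this context
        alt = COMPLEMENT[channel.alt_base]
    alt_reads = int(rng.binomial(depth, vaf_p))
    return SomaticVariant(
        chrom=chrom, pos=pos1, ref_allele=ref_base, alt_allele=alt,
        total_depth=depth, alt_depth=alt_reads,
    )


@dataclass
class TumorPair:
    """Two simulated tumors plus the full truth table."""

    tumor_a: list
    tumor_b: list
    truth: pd.DataFrame
    reference: Mapping[str, str]


def simulate_tumor_pair(
    config: SimulationConfig,
    reference: Mapping[str, str] | None = None,
    signatures: SignatureSet | None = None,
) -> TumorPair:
    """Plant shared early mutations in both tumors, then private clonal and
    subclonal mutations with channels from the configured mixture.

    Clonal variants draw reads at VAF purity/2; subclonal variants at
    cell_fraction/2 with the cell fraction uniform over
    ``config.subclonal_cell_fraction``.  The truth table records every
    variant's tumor, stratum, generating signature and shared status.
    """
    if signatures is None:
        signatures = load_bundled_signatures()
    seeds = config.spawn(4)
    if reference is None:
        reference = simulate_reference(
            config.n_contigs, config.contig_length, config.gc_fraction, seed=seeds[0]
        )
    rng = np.random.default_rng(seeds[1])
    names, fracs, P = _mixture_matrix(config.signature_mixture, signatures)
    sites = _positions_by_context(reference)
    used: set = set()

    def draw_variants(n, stratum, shared):
        out = []
        sig_idx = rng.choice(len(names), size=n, p=fracs)
        chan_idx = np.array([rng.choice(N_CHANNELS, p=P[s]) for s in sig_idx])
        for s, c in zip(sig_idx, chan_idx):
            ctx = CHANNEL_TO_TRINUC32[c]
            pool = sites[ctx]
            if not pool:
                raise ValueError(f"no reference site carries context {c}")
            for _ in range(1000):
                chrom, pos1 = pool[rng.integers(len(pool))]
                if (chrom, pos1) not in used:
                    break
            else:
                raise ValueError("mutation count exceeds available context positions")
            used.add((chrom, pos1))
            if stratum == "clonal":
                vaf_p = config.purity / 2
            else:
                cf = rng.uniform(*config.subclonal_cell_fraction)
                vaf_p = cf / 2
            out.append(
                (
                    _variant_at(reference, chrom, pos1, CHANNELS[c], rng, config.depth, vaf_p),
                    names[s], stratum, shared,
                )
            )
        return out

    n_sub = int(round(config.n_mutations * config.subclonal_fraction))
    n_clonal = config.n_mutations - n_sub
    shared = draw_variants(config.shared_early_mutations, "clonal", True)
    rows = []
    tumors = {"A": [], "B": []}
    for tumor in ("A", "B"):
        for v, sig, stratum, sh in shared:
            # identical genomic variant in both tumors; independent reads
            v2 = SomaticVariant(
                v.chrom, v.pos, v.ref_allele, v.alt_allele,
                total_depth=config.depth,
                alt_depth=int(rng.binomial(config.depth, config.purity / 2)),
            )
            tumors[tumor].append(v2)
            rows.append((tumor, *v2.key, sig, stratum, True))
        for v, sig, stratum, sh in draw_variants(n_clonal, "clonal", False):
            tumors[tumor].append(v)
            rows.append((tumor, *v.key, sig, stratum, False))
        for v, sig, stratum, sh in draw_variants(n_sub, "subclonal", False):
            tumors[tumor].append(v)
            rows.append((tumor, *v.key, sig, stratum, False))
    truth = pd.DataFrame(
        rows,
        columns=["tumor", "chrom", "pos", "ref", "alt", "signature", "stratum", "shared"],
    )
    return TumorPair(tumor_a=tumors["A"], tumor_b=tumors["B"], truth=truth, reference=reference)


def write_vcf(variants, reference: Mapping[str, str], path, sample: str = "TUMOR") -> Path:
    """Write variants as a minimal plain-text VCF 4.2 with DP/AD FORMAT fields."""
    path = Path(path)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    ]
    for name, seq in reference.items():
        lines.append(f"##contig=<ID={name},length={len(seq)}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample)
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
        ref_reads = v.total_depth - v.alt_depth
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref_allele}\t{v.alt_allele}\t.\tPASS\t.\t"
            f"DP:AD\t{v.total_depth}:{ref_reads},{v.alt_depth}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Duplex panel
# ---------------------------------------------------------------------------

@dataclass
class DuplexSimulation:
    panel: DuplexPanel
    calls: DuplexCallSet
    truth_burden: dict
    reference: Mapping[str, str]


def simulate_duplex_panel(
    config: SimulationConfig,
    reference: Mapping[str, str] | None = None,
    signatures: SignatureSet | None = None,
) -> DuplexSimulation:
    """A panel of ``n_panel_intervals`` intervals totaling ``panel_size`` bp,
    overdispersed per-position duplex depth around the configured mean, and
    Poisson calls at the configured true per-genome burden per signature.

    The genome trinucleotide composition is taken from the simulated
    reference and rescaled to ``config.genome_size`` by the consumer, so a
    megabase-scale reference stands in for a full genome at the correct
    per-base call rates.
    """
    if signatures is None:
        signatures = load_bundled_signatures()
    seeds = config.spawn(4)
    if reference is None:
        reference = simulate_reference(
            config.n_contigs, config.contig_length, config.gc_fraction, seed=seeds[0]
        )
    rng = np.random.default_rng(seeds[3])
    burden = dict(config.duplex_burden_per_genome)
    names = list(burden)
    B = np.array([burden[n] for n in names], dtype=float)
    if (B < 0).any():
        raise ValueError("negative burden")

    # intervals: non-overlapping, spread across contigs
    contigs = list(reference)
    per = config.panel_size // config.n_panel_intervals
    intervals = []
    margin = per + 10
    for i in range(config.n_panel_intervals):
        chrom = contigs[i % len(contigs)]
        L = len(reference[chrom])
        while True:
            start = int(rng.integers(1, L - margin))
            cand = (chrom, start, start + per)
            if all(
                c != chrom or end <= start or s >= start + per for c, s, end in intervals
            ):
                intervals.append(cand)
                break
    # overdispersed depth: gamma-mixture Poisson around the mean
    panel = DuplexPanel.from_reference(intervals, reference, depth=0.0)
    n_pos = len(panel.positions)
    lam = rng.gamma(shape=100.0, scale=config.mean_duplex_depth / 100.0, size=n_pos)
    depth = rng.poisson(lam).astype(float)
    panel = DuplexPanel(
        intervals=panel.intervals,
        positions=panel.positions,
        depth=depth,
        context32=panel.context32,
        genome_composition=panel.genome_composition,
    )

    calls = simulate_panel_calls(
        panel, reference, burden, signatures=signatures,
        genome_size=config.genome_size, seed=rng,
    )
    return DuplexSimulation(
        panel=panel,
        calls=calls,
        truth_burden=burden,
        reference=reference,
    )


def simulate_panel_calls(
    panel: DuplexPanel,
    reference: Mapping[str, str],
    burden_per_genome: Mapping[str, float],
    signatures: SignatureSet | None = None,
    genome_size: float = 6.2e9,
    seed=None,
    label: str = "duplex-sim",
) -> DuplexCallSet:
    """Draw one sample's duplex calls on an existing panel.

    Expected calls in channel c are ``burden_c / G_c * D_c`` (per-genome
    channel burden diluted to a per-sequenced-base rate, times the duplex
    bases interrogated at matching contexts); realized counts are Poisson and
    each call is placed at a depth-weighted random context-matched position.
    """
    if signatures is None:
        signatures = load_bundled_signatures()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = list(burden_per_genome)
    B = np.array([burden_per_genome[n] for n in names], dtype=float)
    if (B < 0).any():
        raise ValueError("negative burden")
    ctx_idx = np.asarray(CHANNEL_TO_TRINUC32)
    if names:
        P = signatures.subset(names).matrix
        b_c = B @ P  # per-genome burden per channel
        comp = panel.genome_composition
        G_c = (comp / comp.sum() * genome_size)[ctx_idx]
        D_c = panel.panel_composition[ctx_idx]
        lam_c = np.where(G_c > 0, b_c / G_c, 0.0) * D_c
        n_calls = rng.poisson(lam_c)
    else:
        n_calls = np.zeros(N_CHANNELS, dtype=int)

    depth_by_pos: dict = dict(zip(panel.positions, panel.depth))
    pos_by_ctx: dict = {}
    weights_by_ctx: dict = {}
    for (chrom, pos1), ctx, d in zip(panel.positions, panel.context32, panel.depth):
        pos_by_ctx.setdefault(int(ctx), []).append((chrom, pos1))
        weights_by_ctx.setdefault(int(ctx), []).append(float(d))
    calls = []
    for c in range(N_CHANNELS):
        if n_calls[c] == 0:
            continue
        ctx = CHANNEL_TO_TRINUC32[c]
        pool = pos_by_ctx.get(ctx, [])
        if not pool:
            raise ValueError(f"panel carries no site for channel {CHANNEL_LABELS[c]}")
        w = np.asarray(weights_by_ctx[ctx])
        picks = rng.choice(len(pool), size=int(n_calls[c]), p=w / w.sum())
        for k in picks:
            chrom, pos1 = pool[k]
            ref_base = reference[chrom][pos1 - 1].upper()
            alt = CHANNELS[c].alt_base if ref_base in PYRIMIDINES else COMPLEMENT[CHANNELS[c].alt_base]
            calls.append(
                SomaticVariant(
                    chrom=chrom, pos=pos1, ref_allele=ref_base, alt_allele=alt,
                    total_depth=int(depth_by_pos[(chrom, pos1)]), alt_depth=1,
                )
            )
    return DuplexCallSet(calls=calls, sample_label=label)


def write_panel(panel: DuplexPanel, bed_path, depth_path) -> None:
    """Write the panel as BED intervals plus a per-position depth TSV."""
    with open(bed_path, "w") as fh:
        for chrom, start, end in panel.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")
    with open(depth_path, "w") as fh:
        fh.write("chrom\tpos\tduplex_depth\n")
        for (chrom, pos1), d in zip(panel.positions, panel.depth):
            fh.write(f"{chrom}\t{pos1}\t{d:g}\n")
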