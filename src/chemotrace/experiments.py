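"""Simulation experiments that characterize the pipeline's operating traits.

Each function here measures one property of the method under the study
conditions the package targets — test size under a pure clock-like null, power
at a therapy-related-AML-scale platinum burden, activity-recovery error,
duplex-extrapolation recovery, end-to-end verdict accuracy, and lineage-class
recovery.  They are used by the test suite and the reproduction script, and
are exposed so users can rerun them at other settings.

All randomness flows from a single seed through ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import numpy as np

from .catalog import MutationCatalog96
from .duplex import DuplexBurdenModel
from .lineage import compare_clonal_sets
from .pipeline import analyze_footprint_timing
from .signatures import (
    SignatureSet,
    _fit_batch,
    _lr_statistics_batch,
    _poisson_loglik,
    calibrate_activity,
    load_bundled_signatures,
    mixture_chi2_pvalue,
)
from .simulate import (
    SimulationConfig,
    simulate_catalogs,
    simulate_duplex_panel,
    simulate_panel_calls,
    simulate_reference,
    simulate_tumor_pair,
)
from .timing import VERDICTS

BASELINE_NAMES = ("SBS1", "SBS5", "SBS40")

#: fixed split of the non-platinum (age-related) mutation share across the
#: clock-like baseline when a simulation needs one
AGE_MIX = {"SBS1": 0.2, "SBS5": 0.6, "SBS40": 0.2}


def _sigs(baseline=BASELINE_NAMES, candidate="SBS31"):
    sigs = load_bundled_signatures()
    base = sigs.subset(list(baseline))
    return sigs, base, sigs[candidate]


def _mixture(platinum_fraction: float, candidate: str = "SBS31") -> dict:
    mix = {k: v * (1.0 - platinum_fraction) for k, v in AGE_MIX.items()}
    if platinum_fraction > 0:
        mix[candidate] = platinum_fraction
    return mix


def presence_test_size(
    n_mutations: int = 2000,
    n_replicates: int = 1000,
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed=None,
    run_bootstrap: bool = True,
) -> dict:
    """Empirical rejection rate of the presence test under a pure-SBS5 null.

    Catalogs are drawn from SBS5 alone; the test asks for SBS31 on the
    clock-like baseline.  The bootstrap arm reproduces the packaged bootstrap
    test's accept/reject decision exactly while curtailing each replicate's
    resampling as soon as the decision is determined (once the exceedance
    count can no longer fall below the rejection threshold, further draws
    cannot change the decision).
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    _, base, cand = _sigs()
    full = base.with_profile(cand)
    X, _ = simulate_catalogs({"SBS5": 1.0}, n_mutations, n_replicates, seed=ss[0])

    E0 = _fit_batch(X, base.matrix)
    lr_obs = np.maximum(
        2.0 * (
            _poisson_loglik(X, _fit_batch(X, full.matrix) @ full.matrix)
            - _poisson_loglik(X, E0 @ base.matrix)
        ),
        0.0,
    )
    out = {
        "asymptotic_rejection_rate": float(
            np.mean([mixture_chi2_pvalue(l) <= alpha for l in lr_obs])
        ),
        "n_replicates": n_replicates,
        "alpha": alpha,
    }
    if not run_bootstrap:
        return out

    reject_threshold = int(np.floor(alpha * (n_boot + 1) - 1))  # max exceedances to reject
    rng = np.random.default_rng(ss[1])
    rejected = 0
    for r in range(n_replicates):
        mu0 = E0[r] @ base.matrix
        exceed, drawn = 0, 0
        for chunk in (125, n_boot - 125):
            Xb = rng.poisson(mu0, size=(chunk, X.shape[1])).astype(float)
            lr_null = _lr_statistics_batch(
                Xb, base.matrix, full.matrix, tol=1e-6, omega=1.8,
                init0=E0[r], init1=np.append(E0[r], 0.0),
            )
            exceed += int((lr_null >= lr_obs[r] - 1e-12).sum())
            drawn += chunk
            if exceed > reject_threshold:  # decision fixed: cannot reject
                break
        if drawn == n_boot and exceed <= reject_threshold:
            rejected += 1
    out["bootstrap_rejection_rate"] = rejected / n_replicates
    out["n_boot"] = n_boot
    return out


def presence_test_power(
    n_mutations: int = 2231,
    platinum_activity: float = 932.0,
    n_replicates: int = 200,
    alpha: float = 0.05,
    seed=None,
) -> float:
    """Rejection rate when the platinum signature truly contributes
    ``platinum_activity`` of ``n_mutations`` (defaults: the tAML clonal
    stratum's scale) against the clock-like baseline."""
    _, base, cand = _sigs()
    full = base.with_profile(cand)
    mix = _mixture(platinum_activity / n_mutations)
    X, _ = simulate_catalogs(mix, n_mutations, n_replicates, seed=seed)
    lr = _lr_statistics_batch(X, base.matrix, full.matrix)
    return float(np.mean([mixture_chi2_pvalue(l) <= alpha for l in lr]))


def calibration_zero_coverage(
    n_mutations: int = 2231,
    n_replicates: int = 200,
    coverage: float = 0.95,
    seed=None,
) -> float:
    """Fraction of truly-platinum-free catalogs whose calibrated activity
    interval contains zero."""
    ss = np.random.SeedSequence(seed).spawn(n_replicates + 1)
    _, base, cand = _sigs()
    X, _ = simulate_catalogs(_mixture(0.0), n_mutations, n_replicates, seed=ss[0])
    hits = 0
    for r in range(n_replicates):
        cal = calibrate_activity(
            MutationCatalog96(X[r]), base, cand, coverage=coverage, seed=ss[r + 1]
        )
        hits += cal.interval[0] <= 0.0 <= cal.interval[1]
    return hits / n_replicates


def exposure_recovery(
    mixture: dict | None = None,
    n_mutations: int = 2000,
    n_replicates: int = 200,
    seed=None,
) -> float:
    """Mean absolute relative error of fitted activities against the realized
    per-signature truth, over replicate mixture catalogs."""
    mixture = mixture or {"SBS5": 0.5, "SBS1": 0.2, "SBS31": 0.3}
    sigs = load_bundled_signatures(list(mixture))
    X, truth = simulate_catalogs(mixture, n_mutations, n_replicates, seed=seed)
    E = _fit_batch(X, sigs.matrix)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(E - truth) / np.where(truth > 0, truth, np.nan)
    return float(np.nanmean(rel))


def duplex_recovery(
    true_burdens=(68.0, 150.0, 388.0),
    n_replicates: int = 100,
    background: dict | None = None,
    coverage: float = 0.95,
    n_boot: int = 1000,
    seed=None,
) -> dict:
    """Recovery of the platinum per-genome burden from a simulated panel.

    One 48 kb / 20-interval panel at ~20,000X duplex depth is built once; for
    each true platinum burden, ``n_replicates`` independent call sets are
    drawn on it (over an age-related background of 150 mutations/genome) and
    the genome-wide platinum burden re-estimated.  Reports the mean relative
    error of the point estimate and the fraction of replicates whose
    ``coverage`` interval contains the truth, per burden level.
    """
    background = background if background is not None else {"SBS5": 120.0, "SBS1": 30.0}
    ss = np.random.SeedSequence(seed).spawn(2)
    cfg = SimulationConfig(seed=int(ss[0].generate_state(1)[0] % 2**31))
    cfg.duplex_burden_per_genome = {}
    sim = simulate_duplex_panel(cfg)
    panel, reference = sim.panel, sim.reference
    sigs = load_bundled_signatures(["SBS1", "SBS5", "SBS40", "SBS31"])
    rng_seeds = ss[1].spawn(len(true_burdens) * n_replicates * 2)
    results = {}
    k = 0
    for burden in true_burdens:
        errs, covered = [], 0
        truth = dict(background)
        truth["SBS31"] = float(burden)
        for _ in range(n_replicates):
            calls = simulate_panel_calls(
                panel, reference, truth, genome_size=cfg.genome_size, seed=rng_seeds[k]
            )
            est = DuplexBurdenModel(
                calls, panel, sigs, reference, genome_size=cfg.genome_size
            ).fit(coverage=coverage, n_boot=n_boot, seed=rng_seeds[k + 1])
            k += 2
            point = est.mutations_per_genome_by_signature["SBS31"]
            lo, hi = est.by_signature_intervals["SBS31"]
            errs.append(abs(point - burden) / burden)
            covered += lo <= burden <= hi
        results[burden] = {
            "mean_relative_error": float(np.mean(errs)),
            "interval_coverage": covered / n_replicates,
        }
    results["overall_mean_relative_error"] = float(
        np.mean([results[b]["mean_relative_error"] for b in true_burdens])
    )
    return results


#: stratum compositions mimicking the three observed footprint patterns:
#: (clonal n, clonal platinum fraction, subclonal n, subclonal platinum fraction)
VERDICT_PATTERNS = {
    "post_exposure_clonal_sweep": (2231, 932.0 / 2231.0, 300, 0.2),
    "pre_existing_multicellular": (89, 0.0, 1000, 0.3),
    "indeterminate": (1000, 0.0, 300, 0.0),
}


def verdict_accuracy(
    pattern: str,
    n_replicates: int = 100,
    alpha: float = 0.01,
    n_calibration_replicates: int = 100,
    seed=None,
) -> float:
    """Fraction of synthetic case reconstructions of one footprint pattern
    that the end-to-end pipeline (strict mode) resolves to the correct
    verdict.  Patterns are scaled to the mutation counts of the corresponding
    observed second-tumor strata."""
    if pattern not in VERDICT_PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}; one of {list(VERDICT_PATTERNS)}")
    n_cl, f_cl, n_sub, f_sub = VERDICT_PATTERNS[pattern]
    ss = np.random.SeedSequence(seed).spawn(3)
    Xc, _ = simulate_catalogs(_mixture(f_cl), n_cl, n_replicates, seed=ss[0])
    Xs, _ = simulate_catalogs(_mixture(f_sub), n_sub, n_replicates, seed=ss[1])
    child = ss[2].spawn(n_replicates)
    correct = 0
    for r in range(n_replicates):
        verdict = analyze_footprint_timing(
            MutationCatalog96(Xc[r], label="clonal"),
            MutationCatalog96(Xs[r], label="subclonal"),
            alpha=alpha,
            strict=True,
            n_calibration_replicates=n_calibration_replicates,
            seed=child[r],
        )
        correct += verdict.verdict == pattern
    return correct / n_replicates


def _lineage_normals(pair, planted: int, depth: int, rng, noiseless: bool):
    """Observations of the shared variants in 10 normal tissues plus blood.

    For a single planted shared mutation the scenario is an early mosaic:
    present in every tissue at cell fraction ~0.16 (VAF 0.08).  For several
    planted mutations the scenario is a shared founding clone absent from
    normal tissue (true VAF 0, hence zero alt reads under binomial
    read sampling).
    """
    shared = pair.truth[pair.truth.shared & (pair.truth.tumor == "A")]
    tissues = ["blood"] + [f"tissue{i}" for i in range(1, 10)]
    normals: dict = {t: [] for t in tissues}
    from .catalog import SomaticVariant

    for _, row in shared.iterrows():
        for t in tissues:
            if planted == 1:  # early mosaic, present everywhere at low VAF
                vaf = 0.08
                alt = int(round(vaf * depth)) if noiseless else int(rng.binomial(depth, vaf))
            else:  # absent from normal tissue: true VAF 0
                alt = 0
            normals[t].append(
                SomaticVariant(row.chrom, row.pos, row.ref, row.alt,
                               total_depth=depth, alt_depth=alt)
            )
    return normals


EXPECTED_LINEAGE_CLASS = {
    0: "independent_lineages",
    1: "ambiguous_de_novo_vs_mosaic",
    5: "common_early_clone",
}


def lineage_recovery(
    planted_counts=(0, 1, 5),
    n_replicates: int = 20,
    depth: int = 120,
    noiseless: bool = False,
    seed=None,
) -> dict:
    """Fraction of simulated tumor pairs whose planted lineage class is
    recovered, per planted shared-mutation count."""
    ss = np.random.SeedSequence(seed).spawn(2)
    reference = simulate_reference(n_contigs=1, contig_length=100_000, seed=ss[0])
    child = ss[1].spawn(len(planted_counts) * n_replicates)
    out = {}
    k = 0
    for planted in planted_counts:
        correct = 0
        for _ in range(n_replicates):
            rng = np.random.default_rng(child[k])
            cfg = SimulationConfig(
                seed=int(child[k].generate_state(1)[0] % 2**31),
                n_mutations=120, depth=depth, shared_early_mutations=planted,
            )
            k += 1
            pair = simulate_tumor_pair(cfg, reference)
            normals = _lineage_normals(pair, planted, depth, rng, noiseless)
            clonal_keys = {
                t: set(
                    map(tuple, pair.truth.loc[
                        (pair.truth.tumor == t) & (pair.truth.stratum == "clonal"),
                        ["chrom", "pos", "ref", "alt"],
                    ].itertuples(index=False))
                )
                for t in ("A", "B")
            }
            report = compare_clonal_sets(
                [v for v in pair.tumor_a if v.key in clonal_keys["A"]],
                [v for v in pair.tumor_b if v.key in clonal_keys["B"]],
                normals, reference_normal="blood",
            )
            correct += report.classification == EXPECTED_LINEAGE_CLASS[planted]
        out[planted] = correct / n_replicates
    return out
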