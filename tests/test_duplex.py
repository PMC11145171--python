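"""Duplex-panel burden extrapolation and per-day mutation rates."""

import numpy as np
import pytest

from chemotrace.catalog import SomaticVariant
from chemotrace.duplex import (
    CallOutsidePanelError,
    DuplexBurdenModel,
    DuplexCallSet,
    DuplexPanel,
    ExposureHistory,
    estimate_genomewide_burden,
    panel_profile,
    per_day_rates,
)
from chemotrace.signatures import ExposureVector, load_bundled_signatures
from chemotrace.simulate import SimulationConfig, simulate_duplex_panel, simulate_panel_calls


@pytest.fixture(scope="module")
def toy_panel(small_reference):
    """A composition-matched toy panel: one 50 kb interval at uniform depth 20,
    genome composition taken from the same reference (so the channel-wise
    correction collapses to the scalar genome_size / effective_bases)."""
    return DuplexPanel.from_reference(
        [("chr1", 100, 50_100)], small_reference, depth=20.0
    )


@pytest.fixture(scope="module")
def fit_signatures():
    return load_bundled_signatures(["SBS1", "SBS5", "SBS40", "SBS31"])


def _calls_at(reference, panel, n, trinuc="ACT", alt="T", start=200):
    """n C>alt SNV calls at distinct panel positions sharing the exact
    reference trinucleotide (hence the same channel)."""
    seq = reference["chr1"]
    calls, pos = [], start
    while len(calls) < n:
        if seq[pos - 2 : pos + 1] == trinuc:
            calls.append(
                SomaticVariant("chr1", pos, trinuc[1], alt, total_depth=20, alt_depth=1)
            )
        pos += 1
    return calls


def test_panel_bookkeeping(toy_panel):
    assert toy_panel.panel_size == 50_000
    assert toy_panel.effective_duplex_bases == pytest.approx(50_000 * 20.0)
    assert toy_panel.panel_composition.sum() <= 50_000 * 20.0
    assert toy_panel.contains("chr1", 101)
    assert not toy_panel.contains("chr1", 100)  # BED half-open start


def test_panel_profile_counts(small_reference, toy_panel):
    empty = panel_profile(DuplexCallSet([], "s"), toy_panel, small_reference)
    assert empty.n_total == 0
    calls = _calls_at(small_reference, toy_panel, 3)
    cat = panel_profile(DuplexCallSet(calls, "s"), toy_panel, small_reference)
    assert cat.n_total == 3


def test_call_outside_panel_rejected(small_reference, toy_panel):
    outside = [SomaticVariant("chr1", 99_000, "C", "T", 20, 1)]
    with pytest.raises(CallOutsidePanelError, match="chr1:99000"):
        panel_profile(DuplexCallSet(outside, "s"), toy_panel, small_reference)


def test_duplicate_calls_count_once(small_reference, toy_panel):
    calls = _calls_at(small_reference, toy_panel, 1) * 3
    cat = panel_profile(DuplexCallSet(calls, "s"), toy_panel, small_reference)
    assert cat.n_total == 1


def test_uniform_toy_closed_form(small_reference, fit_signatures):
    """3 calls over 1e6 effective duplex bases of a composition-matched panel
    with a 3e9 genome extrapolate to 9000 mutations per genome."""
    base = DuplexPanel.from_reference([("chr1", 100, 50_100)], small_reference, depth=20.0)
    # genome composition proportional to the panel's: the channel-wise
    # correction must collapse to the scalar genome_size / effective_bases
    panel = DuplexPanel(
        intervals=base.intervals, positions=base.positions, depth=base.depth,
        context32=base.context32, genome_composition=base.panel_composition,
    )
    calls = _calls_at(small_reference, panel, 3)
    est = estimate_genomewide_burden(
        DuplexCallSet(calls, "toy"), panel, fit_signatures, small_reference,
        genome_size=3e9, n_boot=100, seed=1,
    )
    assert panel.effective_duplex_bases == pytest.approx(1e6)
    assert est.mutations_per_genome_total == pytest.approx(9000.0, rel=1e-6)
    assert sum(est.mutations_per_genome_by_signature.values()) == pytest.approx(
        est.mutations_per_genome_total, abs=1e-6
    )


def test_zero_calls_gives_zero_burden_with_positive_upper(small_reference, toy_panel,
                                                          fit_signatures):
    est = estimate_genomewide_burden(
        DuplexCallSet([], "none"), toy_panel, fit_signatures, small_reference,
        genome_size=6.2e9, seed=2,
    )
    assert est.mutations_per_genome_total == 0.0
    assert est.interval[0] == 0.0
    assert est.interval[1] > 0.0


def test_depth_invariance(small_reference, fit_signatures):
    """Doubling per-position depth while doubling the call counts leaves the
    point estimate unchanged."""
    p1 = DuplexPanel.from_reference([("chr1", 100, 50_100)], small_reference, depth=20.0)
    p2 = DuplexPanel.from_reference([("chr1", 100, 50_100)], small_reference, depth=40.0)
    calls = _calls_at(small_reference, p1, 4)
    more = calls + _calls_at(small_reference, p1, 4, start=30_000)
    e1 = estimate_genomewide_burden(
        DuplexCallSet(calls, "a"), p1, fit_signatures, small_reference, n_boot=50, seed=3
    )
    e2 = estimate_genomewide_burden(
        DuplexCallSet(more, "b"), p2, fit_signatures, small_reference, n_boot=50, seed=3
    )
    assert e2.mutations_per_genome_total == pytest.approx(
        e1.mutations_per_genome_total, rel=1e-6
    )


def test_vaf_ceiling_excludes_clonal_leakage(small_reference, toy_panel):
    v = _calls_at(small_reference, toy_panel, 1)[0]
    clonal = SomaticVariant(v.chrom, v.pos, v.ref_allele, v.alt_allele,
                            total_depth=20, alt_depth=10)  # VAF 0.5 >> ceiling
    cat = panel_profile(DuplexCallSet([clonal], "s"), toy_panel, small_reference)
    assert cat.n_total == 0


def test_simulated_panel_recovery_single(fit_signatures):
    """One simulated panel sample at the highest observed burden: the
    estimate lands within a factor consistent with Poisson noise and the
    interval brackets the point."""
    cfg = SimulationConfig(seed=99)
    cfg.duplex_burden_per_genome = {"SBS31": 388.0, "SBS5": 120.0, "SBS1": 30.0}
    sim = simulate_duplex_panel(cfg)
    est = DuplexBurdenModel(
        sim.calls, sim.panel, fit_signatures, sim.reference, genome_size=cfg.genome_size
    ).fit(n_boot=200, seed=5)
    platinum = est.mutations_per_genome_by_signature["SBS31"]
    assert platinum == pytest.approx(388.0, rel=0.5)
    lo, hi = est.by_signature_intervals["SBS31"]
    assert lo <= platinum <= hi


class TestPerDayRates:
    def test_platinum_rate_at_reported_scale(self):
        """932 platinum mutations over a 4-day course: 233 per treatment day."""
        exp = ExposureVector(names=["SBS31", "SBS5"], activities=[932.0, 1136.0])
        hist = ExposureHistory.from_years(treatment_days=4, age_years=17.0)
        rates = per_day_rates(exp, hist)
        assert rates["platinum_per_treatment_day"] == pytest.approx(233.0)
        assert rates["age_related_per_life_day"] == pytest.approx(0.1830, abs=5e-4)
        assert round(rates["age_related_per_life_day"], 2) == 0.18

    def test_zero_burden_zero_rate(self):
        exp = ExposureVector(names=["SBS31", "SBS5"], activities=[0.0, 0.0])
        rates = per_day_rates(exp, ExposureHistory.from_years(4, 10.0))
        assert rates["platinum_per_treatment_day"] == 0.0
        assert rates["age_related_per_life_day"] == 0.0

    def test_history_validation(self):
        with pytest.raises(ValueError):
            ExposureHistory(treatment_days=0, age_at_sampling_days=100.0)
        with pytest.raises(ValueError):
            ExposureHistory(treatment_days=4, age_at_sampling_days=100.0,
                            age_at_treatment_start_days=200.0)
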