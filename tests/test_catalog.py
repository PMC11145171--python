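"""Catalog construction, context extraction and clonality partitioning."""

import numpy as np
import pytest
from scipy import stats

from chemotrace.catalog import (
    AmbiguousContextError,
    MutationCatalog96,
    ReferenceMismatchError,
    SomaticVariant,
    build_catalog,
    extract_context,
    partition_clonality,
    read_vcf,
)
from chemotrace.channels import CHANNEL_LABELS, COMPLEMENT
from chemotrace.simulate import simulate_tumor_pair, SimulationConfig, write_vcf


def test_extract_context_pyrimidine():
    ref = {"chr1": "AACTG"}
    v = SomaticVariant("chr1", 3, "C", "T", 100, 50)
    assert extract_context(v, ref).label == "A[C>T]T"


def test_extract_context_purine_normalized():
    ref = {"chr1": "AAGTG"}  # AGT centered on G; G>C -> revcomp ACT, C>G
    v = SomaticVariant("chr1", 3, "G", "C", 100, 50)
    assert extract_context(v, ref).label == "A[C>G]T"


def test_extract_context_errors():
    ref = {"chr1": "AACTG", "chr2": "ANCTG"}
    with pytest.raises(ReferenceMismatchError, match="chr1:3"):
        extract_context(SomaticVariant("chr1", 3, "G", "A", 10, 5), ref)
    with pytest.raises(AmbiguousContextError):
        extract_context(SomaticVariant("chr2", 3, "C", "T", 10, 5), ref)


def test_variant_validation():
    with pytest.raises(ValueError):
        SomaticVariant("chr1", 1, "C", "C", 10, 5)
    with pytest.raises(ValueError):
        SomaticVariant("chr1", 1, "C", "T", 10, 20)
    v = SomaticVariant("chr1", 1, "C", "T", 120, 60)
    assert v.vaf == pytest.approx(0.5)
    assert not SomaticVariant("chr1", 1, "CT", "C", 10, 5).is_snv


def test_build_catalog_counts_and_skips():
    ref = {"chr1": "AACTGACTG"}
    snv = SomaticVariant("chr1", 3, "C", "T", 100, 50)
    indel = SomaticVariant("chr1", 3, "CT", "C", 100, 50)
    cat = build_catalog([snv, snv, snv, indel], ref, label="toy")
    assert cat.n_total == 3
    assert cat.to_series()["A[C>T]T"] == 3
    assert (cat.counts > 0).sum() == 1
    empty = build_catalog([], ref)
    assert empty.n_total == 0 and (empty.counts == 0).all()


def test_catalog_tsv_roundtrip(tmp_path):
    counts = np.arange(96, dtype=float)
    cat = MutationCatalog96(counts, label="rt")
    path = tmp_path / "catalog.tsv"
    cat.to_tsv(path)
    assert len(path.read_text().splitlines()) == 97
    back = MutationCatalog96.from_tsv(path, label="rt")
    np.testing.assert_array_equal(back.counts, counts)


def test_catalog_strand_symmetry(small_reference):
    """Reverse-complementing the genome and every variant leaves the catalog
    unchanged."""
    cfg = SimulationConfig(seed=7, n_mutations=300, n_contigs=1, contig_length=100_000)
    pair = simulate_tumor_pair(cfg, small_reference)
    variants = pair.tumor_a
    cat = build_catalog(variants, small_reference)

    seq = small_reference["chr1"]
    L = len(seq)
    rc_ref = {"chr1": "".join(COMPLEMENT[b] for b in reversed(seq))}
    rc_variants = [
        SomaticVariant("chr1", L - v.pos + 1, COMPLEMENT[v.ref_allele],
                       COMPLEMENT[v.alt_allele], v.total_depth, v.alt_depth)
        for v in variants
    ]
    rc_cat = build_catalog(rc_variants, rc_ref)
    np.testing.assert_array_equal(cat.counts, rc_cat.counts)


def test_catalog_roundtrip_goodness_of_fit(signatures):
    """A catalog built from 10,000 variants simulated from a known channel
    distribution matches that distribution (chi-square GOF p > 0.01)."""
    from chemotrace.simulate import simulate_reference

    reference = simulate_reference(n_contigs=1, contig_length=400_000, seed=3)
    mixture = {"SBS5": 0.6, "SBS1": 0.2, "SBS40": 0.2}
    cfg = SimulationConfig(seed=11, n_mutations=10_000, subclonal_fraction=0.0,
                           signature_mixture=mixture)
    pair = simulate_tumor_pair(cfg, reference)
    cat = build_catalog(pair.tumor_a, reference)
    probs = sum(f * signatures[n].probs for n, f in mixture.items())
    res = stats.chisquare(cat.counts, probs * cat.n_total)
    assert cat.n_total == 10_000
    assert res.pvalue > 0.01


class TestPartitionClonality:
    def test_trivial_examples(self):
        clonal_v = SomaticVariant("chr1", 1, "C", "T", 120, 60)
        sub_v = SomaticVariant("chr1", 2, "C", "T", 120, 6)
        part = partition_clonality([clonal_v, sub_v], purity=1.0, alpha=0.01)
        assert part.clonal == [clonal_v]
        assert part.subclonal == [sub_v]
        assert part.expected_clonal_vaf == 0.5

    def test_exhaustive_and_deterministic(self, rng):
        variants = [
            SomaticVariant("chr1", i + 1, "C", "T", 120, int(a))
            for i, a in enumerate(rng.integers(0, 120, size=200))
        ] + [SomaticVariant("chr1", 999, "C", "T", 0, 0)]
        p1 = partition_clonality(variants, purity=0.8)
        p2 = partition_clonality(variants, purity=0.8)
        assert len(p1.clonal) + len(p1.subclonal) + len(p1.excluded) == len(variants)
        assert len(p1.excluded) == 1
        assert [v.pos for v in p1.clonal] == [v.pos for v in p2.clonal]

    def test_purity_default_is_twice_median_vaf(self):
        variants = [SomaticVariant("chr1", i + 1, "C", "T", 100, 40) for i in range(9)]
        part = partition_clonality(variants)
        assert part.purity == pytest.approx(0.8)

    def test_misclassification_rate_on_labeled_simulation(self, rng):
        """500 clonal (beta around purity/2) + 500 subclonal (VAF <= 0.1)
        variants at depth 120: misclassification below 5%."""
        purity, depth = 0.8, 120
        clonal_vafs = rng.beta(40 * purity / 2, 40 * (1 - purity / 2), 500)
        sub_vafs = rng.uniform(0.01, 0.1, 500)
        variants, labels = [], []
        for i, vaf in enumerate(np.concatenate([clonal_vafs, sub_vafs])):
            variants.append(
                SomaticVariant("chr1", i + 1, "C", "T", depth, int(rng.binomial(depth, vaf)))
            )
            labels.append(i < 500)
        part = partition_clonality(variants, purity=purity, alpha=0.01)
        called_clonal = {v.pos for v in part.clonal}
        errors = sum(
            (v.pos in called_clonal) != lab for v, lab in zip(variants, labels)
        )
        assert errors / len(variants) < 0.05


def test_vcf_roundtrip(tmp_path, small_reference):
    cfg = SimulationConfig(seed=5, n_mutations=50, n_contigs=1, contig_length=100_000)
    pair = simulate_tumor_pair(cfg, small_reference)
    path = write_vcf(pair.tumor_a, small_reference, tmp_path / "a.vcf")
    back = read_vcf(path)
    assert sorted(v.key for v in back) == sorted(v.key for v in pair.tumor_a)
    by_key = {v.key: v for v in back}
    for v in pair.tumor_a:
        assert by_key[v.key].alt_depth == v.alt_depth
        assert by_key[v.key].total_depth == v.total_depth


def test_profile_plot_smoke(signatures):
    import matplotlib
    matplotlib.use("Agg")
    from chemotrace.signatures import SignatureActivityModel
    from chemotrace.simulate import simulate_catalog

    cat, _ = simulate_catalog({"SBS31": 1.0}, 500, seed=1, label="smoke")
    ax = cat.plot()
    assert ax.get_title() == "smoke"
    res = SignatureActivityModel(cat, signatures.subset(["SBS31", "SBS5"])).fit()
    assert res.plot() is not None
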