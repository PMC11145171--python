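"""Developmental-lineage comparison of two tumors from one patient.

Two tumors that share clonal somatic SNVs must descend from a common mutated
ancestor cell; sharing *no* clonal SNVs means their founding lineages diverged
before either acquired a detectable somatic mutation (for embryonal tumors,
very early in development).  A single shared variant that is also detectable
at low VAF across all normal tissues is ambiguous between a de novo germline
variant and a very early mosaic mutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .catalog import SomaticVariant

logger = logging.getLogger(__name__)

CLASSIFICATIONS = ("independent_lineages", "common_early_clone", "ambiguous_de_novo_vs_mosaic")

#: minimum alt reads for a variant to count as detected in a normal tissue
#: (matches bulk-WGS sensitivity at ~120X)
DETECTION_FLOOR_ALT_READS = 2

#: above this many tumor clonal variants detected at low VAF in one normal
#: tissue, the signal is flagged as metastatic infiltration, not lineage
INFILTRATION_VARIANT_COUNT = 100


class DataIntegrityError(ValueError):
    """Inconsistent reference alleles reported at the same genomic site."""


@dataclass
class SharedMutationReport:
    """Outcome of comparing the clonal mutation sets of two tumors."""

    n_shared_clonal: int
    n_private_a: int
    n_private_b: int
    shared_variants: list
    low_vaf_presence_in_normals: dict
    classification: str
    infiltration_flags: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_shared_clonal": self.n_shared_clonal,
            "n_private_a": self.n_private_a,
            "n_private_b": self.n_private_b,
            "classification": self.classification,
            "shared_variants": [list(v.key) for v in self.shared_variants],
            "low_vaf_presence_in_normals": {
                tissue: [[list(v.key), v.vaf] for v in obs]
                for tissue, obs in self.low_vaf_presence_in_normals.items()
            },
            "infiltration_flags": self.infiltration_flags,
        }


def _check_ref_consistency(variants) -> None:
    seen: dict = {}
    for v in variants:
        site = (v.chrom, v.pos)
        if site in seen and seen[site] != v.ref_allele:
            raise DataIntegrityError(
                f"inconsistent reference alleles at {v.chrom}:{v.pos}: "
                f"{seen[site]!r} vs {v.ref_allele!r}"
            )
        seen.setdefault(site, v.ref_allele)


def _detected(obs: SomaticVariant, floor: int) -> bool:
    return obs.alt_depth >= floor


def compare_clonal_sets(
    clonal_a: Sequence[SomaticVariant],
    clonal_b: Sequence[SomaticVariant],
    normals: Mapping[str, Sequence[SomaticVariant]] | None = None,
    reference_normal: str | None = None,
    detection_floor: int = DETECTION_FLOOR_ALT_READS,
) -> SharedMutationReport:
    """Compare two tumors' clonal SNV sets and classify their relationship.

    Variant identity is (chrom, pos, ref, alt).  ``normals`` maps tissue name
    to the read-level observations of candidate variants in that tissue;
    ``reference_normal`` names the germline-reference tissue (default: first).

    Classification: no shared variants -> ``independent_lineages``; shared
    variants absent (below the ``detection_floor`` alt reads) from the
    reference normal -> ``common_early_clone``; a single shared variant
    detected at low VAF across *all* normals -> ``ambiguous_de_novo_vs_mosaic``
    (cannot distinguish a de novo germline variant from an early mosaic).

    Additionally, any normal tissue in which more than
    :data:`INFILTRATION_VARIANT_COUNT` of one tumor's clonal variants are
    detected at low VAF is flagged as metastatic infiltration rather than
    evidence of lineage sharing.
    """
    normals = dict(normals or {})
    _check_ref_consistency(list(clonal_a) + list(clonal_b) + [v for o in normals.values() for v in o])

    keys_a = {v.key: v for v in clonal_a}
    keys_b = {v.key: v for v in clonal_b}
    shared_keys = sorted(set(keys_a) & set(keys_b))
    shared = [keys_a[k] for k in shared_keys]
    n_private_a = len(keys_a) - len(shared)
    n_private_b = len(keys_b) - len(shared)

    # observations of the shared variants across normals
    normal_obs: dict[str, list] = {}
    for tissue, obs in normals.items():
        hits = [o for o in obs if o.key in set(shared_keys) and _detected(o, detection_floor)]
        if hits:
            normal_obs[tissue] = hits

    if reference_normal is None and normals:
        reference_normal = next(iter(normals))

    if not shared:
        classification = "independent_lineages"
    else:
        in_reference = reference_normal is not None and reference_normal in normal_obs
        present_in_all_normals = bool(normals) and all(
            any(o.key == k for o in normal_obs.get(t, [])) for t in normals for k in shared_keys
        )
        if len(shared) == 1 and present_in_all_normals:
            classification = "ambiguous_de_novo_vs_mosaic"
        elif not in_reference:
            classification = "common_early_clone"
        else:
            classification = "ambiguous_de_novo_vs_mosaic"

    # infiltration guard: one tumor's private clonal variants detected en
    # masse at low VAF in a normal tissue
    infiltration: dict[str, int] = {}
    tumor_keys = set(keys_a) | set(keys_b)
    for tissue, obs in normals.items():
        n_hits = sum(
            1 for o in obs
            if o.key in tumor_keys and _detected(o, detection_floor) and (o.vaf or 0) < 0.3
        )
        if n_hits > INFILTRATION_VARIANT_COUNT:
            infiltration[tissue] = n_hits
            logger.warning(
                "compare_clonal_sets: %d tumor clonal variants detected at low VAF in "
                "normal %s — flagged as metastatic infiltration", n_hits, tissue,
            )

    return SharedMutationReport(
        n_shared_clonal=len(shared),
        n_private_a=n_private_a,
        n_private_b=n_private_b,
        shared_variants=shared,
        low_vaf_presence_in_normals=normal_obs,
        classification=classification,
        infiltration_flags=infiltration,
    )


@dataclass
class TrioGenotypes:
    """Child and parental observations of one candidate variant site.

    ``child_vafs`` maps tissue name -> VAF in that tissue of the child;
    parental VAFs are from blood.  ``None`` for a parent means no data.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    child_vafs: Mapping[str, float]
    mother_vaf: float | None = None
    father_vaf: float | None = None


def classify_trio_variant(
    site: TrioGenotypes,
    het_band: tuple = (0.35, 0.65),
    hom_band: tuple = (0.85, 1.0),
    parent_presence_vaf: float = 0.05,
) -> str:
    """Classify a child variant as inherited, de novo germline, or mosaic.

    Present in a parent (VAF >= ``parent_presence_vaf``) -> ``inherited``.
    Absent from both parents with child VAF inside the heterozygous or
    homozygous band in *every* tissue -> ``de_novo_germline`` (in all cells).
    Absent from parents with VAF below the heterozygous band in at least one
    tissue -> ``mosaic_somatic`` (acquired during embryogenesis, present in a
    fraction of cells).  Missing parental data downgrades the call to
    ``ambiguous`` with a logged warning.
    """
    if site.mother_vaf is None or site.father_vaf is None:
        logger.warning(
            "classify_trio_variant: missing parental data at %s:%d — ambiguous",
            site.chrom, site.pos,
        )
        return "ambiguous"
    if site.mother_vaf >= parent_presence_vaf or site.father_vaf >= parent_presence_vaf:
        return "inherited"
    vafs = list(site.child_vafs.values())
    if not vafs:
        raise ValueError(f"no child observations at {site.chrom}:{site.pos}")
    in_band = [
        het_band[0] <= v <= het_band[1] or hom_band[0] <= v <= hom_band[1] for v in vafs
    ]
    if all(in_band):
        return "de_novo_germline"
    if any(v < het_band[0] for v in vafs):
        return "mosaic_somatic"
    return "ambiguous"
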