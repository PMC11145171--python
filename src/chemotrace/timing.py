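"""Clonal-expansion timing verdicts from footprint presence in the two strata.

The decision rule reads the chemotherapy footprint's presence in the clonal
and subclonal mutation strata of the second tumor:

* footprint among **clonal** mutations — every tumor cell carries
  chemotherapy-made mutations, which requires the whole tumor to descend from
  a single exposed cell: a clonal sweep after the exposure
  (``post_exposure_clonal_sweep``).
* footprint **only among subclonal** mutations — exposed cells contributed
  lineages but no single exposed cell swept; the tumor must already have been
  a multicellular clone at treatment time (``pre_existing_multicellular``).
* footprint in **neither** stratum — no timing information: the footprint may
  be below the detection limit, or the founding cells may have been shielded
  from the drug (``indeterminate``).

The two strata feed one joint decision rule, so no multiple-testing
correction is applied across them.  In strict mode a stratum counts as
"present" only when the test rejects *and* the calibrated activity interval
excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass

from .signatures import CalibrationResult, PresenceTestResult

VERDICTS = ("post_exposure_clonal_sweep", "pre_existing_multicellular", "indeterminate")


@dataclass
class TimingVerdict:
    """Categorical timing outcome with the evidence it was derived from."""

    verdict: str
    clonal_test: PresenceTestResult
    subclonal_test: PresenceTestResult
    alpha: float
    note: str = ""
    clonal_calibration: CalibrationResult | None = None
    subclonal_calibration: CalibrationResult | None = None

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "alpha": self.alpha,
            "note": self.note,
            "clonal": self.clonal_test.to_dict(),
            "subclonal": self.subclonal_test.to_dict(),
        }


def _present(test: PresenceTestResult, alpha: float, calibration) -> bool:
    if test.p_value > alpha:
        return False
    if calibration is not None:
        return calibration.excludes_zero
    return True


def infer_timing(
    clonal_test: PresenceTestResult,
    subclonal_test: PresenceTestResult,
    alpha: float = 0.05,
    clonal_calibration: CalibrationResult | None = None,
    subclonal_calibration: CalibrationResult | None = None,
) -> TimingVerdict:
    """Turn the two stratum-level presence results into a timing verdict.

    ``clonal present`` dominates (clonal + subclonal and clonal-only both mean
    a post-exposure sweep); ``subclonal``-only means a pre-existing
    multicellular clone; neither means indeterminate.  When calibration
    results are supplied, "present" additionally requires the calibrated
    activity interval to exclude zero (strict mode).
    """
    if clonal_test.candidate != subclonal_test.candidate:
        raise ValueError(
            f"stratum tests refer to different candidates: "
            f"{clonal_test.candidate!r} vs {subclonal_test.candidate!r}"
        )
    clonal = _present(clonal_test, alpha, clonal_calibration)
    subclonal = _present(subclonal_test, alpha, subclonal_calibration)
    note = ""
    if clonal:
        verdict = "post_exposure_clonal_sweep"
    elif subclonal:
        verdict = "pre_existing_multicellular"
    else:
        verdict = "indeterminate"
        note = (
            "no footprint detected in either stratum: the exposure footprint may be "
            "below the detection limit, or the founding clone may have been shielded "
            "from the drug"
        )
    return TimingVerdict(
        verdict=verdict,
        clonal_test=clonal_test,
        subclonal_test=subclonal_test,
        alpha=alpha,
        note=note,
        clonal_calibration=clonal_calibration,
        subclonal_calibration=subclonal_calibration,
    )
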