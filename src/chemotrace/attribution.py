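"""Per-mutation signature attribution.

Given fitted activities, the posterior probability that a mutation observed
at channel *c* was generated by signature *s* is

    P(s | c) = e_s * p_s(c) / sum_t e_t * p_t(c)

i.e. the share of the channel's fitted intensity contributed by each active
process.  Attribution should use the exposures of the mutation's clonality
stratum (a clonal driver is attributed with the clonal-fit activities).  When
two candidate signatures are alternatives (as the platinum pair SBS31/SBS35
is), attribution is computed once per alternative fit, yielding a range
rather than a joint estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .channels import TrinucleotideChannel
from .signatures import ExposureVector, SignatureSet


class UndefinedAttributionError(ZeroDivisionError):
    """No active signature places mass on the requested channel."""


@dataclass
class AttributionResult:
    """Per-signature generation probabilities for one channel."""

    channel: TrinucleotideChannel
    per_signature_probability: dict

    def __getitem__(self, name: str) -> float:
        return self.per_signature_probability[name]

    def to_series(self) -> pd.Series:
        return pd.Series(self.per_signature_probability, name=self.channel.label)


def attribute_mutation(
    channel: TrinucleotideChannel | str,
    signatures: SignatureSet,
    exposures: ExposureVector,
) -> AttributionResult:
    """Posterior probability that each signature generated a mutation at
    ``channel``; raises :class:`UndefinedAttributionError` when the channel
    has zero fitted intensity."""
    if isinstance(channel, str):
        channel = TrinucleotideChannel.from_label(channel)
    if list(exposures.names) != signatures.names:
        raise ValueError("exposures not aligned with signatures")
    c = channel.index
    weights = {
        p.name: exposures.activities[i] * p.probs[c]
        for i, p in enumerate(signatures.profiles)
    }
    total = sum(weights.values())
    if total <= 0:
        raise UndefinedAttributionError(
            f"zero total intensity at channel {channel.label}: attribution undefined"
        )
    return AttributionResult(
        channel=channel,
        per_signature_probability={k: v / total for k, v in weights.items()},
    )
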