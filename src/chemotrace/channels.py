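"""The 96 pyrimidine-centered trinucleotide substitution channels.

Single base substitutions are reported on the strand whose reference base is a
pyrimidine (C or T); a purine-reference change is reverse-complemented together
with its flanking bases.  Channels follow the canonical catalog order used by
published signature matrices: the six substitution classes alphabetically
(C>A, C>G, C>T, T>A, T>C, T>G), and within each class the sixteen flanking
contexts alphabetically (A_A, A_C, ..., T_T), giving index
``16 * substitution + 4 * five_prime + three_prime``.
"""

from __future__ import annotations

from dataclasses import dataclass

BASES = "ACGT"
PYRIMIDINES = "CT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

N_CHANNELS = 96
N_CONTEXTS = 32


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (uppercase; N allowed)."""
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


@dataclass(frozen=True)
class TrinucleotideChannel:
    """One of the 96 substitution channels, e.g. ``A[C>T]T``.

    The central base of the written context is always the pyrimidine of the
    substitution; ``index`` is the position in canonical catalog order.
    """

    substitution: str
    context5: str
    context3: str

    def __post_init__(self):
        if self.substitution not in SUBSTITUTIONS:
            raise ValueError(f"not a pyrimidine-centered substitution: {self.substitution!r}")
        for b in (self.context5, self.context3):
            if b not in BASES:
                raise ValueError(f"invalid context base: {b!r}")

    @property
    def index(self) -> int:
        return (
            16 * SUBSTITUTIONS.index(self.substitution)
            + 4 * BASES.index(self.context5)
            + BASES.index(self.context3)
        )

    @property
    def ref_base(self) -> str:
        return self.substitution[0]

    @property
    def alt_base(self) -> str:
        return self.substitution[2]

    @property
    def trinucleotide(self) -> str:
        """Pyrimidine-centered reference trinucleotide, e.g. ``ACT``."""
        return self.context5 + self.ref_base + self.context3

    @property
    def label(self) -> str:
        return f"{self.context5}[{self.substitution}]{self.context3}"

    @classmethod
    def from_label(cls, label: str) -> "TrinucleotideChannel":
        """Parse a label such as ``A[C>T]G``."""
        if len(label) != 7 or label[1] != "[" or label[5] != "]":
            raise ValueError(f"malformed channel label: {label!r}")
        return cls(substitution=label[2:5], context5=label[0], context3=label[6])

    @classmethod
    def from_index(cls, index: int) -> "TrinucleotideChannel":
        if not 0 <= index < N_CHANNELS:
            raise ValueError(f"channel index out of range: {index}")
        sub, rem = divmod(index, 16)
        five, three = divmod(rem, 4)
        return cls(SUBSTITUTIONS[sub], BASES[five], BASES[three])

    @classmethod
    def from_change(cls, ref: str, alt: str, context5: str, context3: str) -> "TrinucleotideChannel":
        """Build a channel from any strand's (ref, alt, flanks), normalizing
        purine-reference changes to the pyrimidine strand."""
        ref, alt = ref.upper(), alt.upper()
        context5, context3 = context5.upper(), context3.upper()
        if ref not in BASES or alt not in BASES:
            raise ValueError(f"invalid alleles: {ref!r}>{alt!r}")
        if ref == alt:
            raise ValueError(f"ref and alt alleles are identical: {ref!r}")
        if ref not in PYRIMIDINES:
            ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
            context5, context3 = COMPLEMENT[context3], COMPLEMENT[context5]
        return cls(f"{ref}>{alt}", context5, context3)


CHANNELS = tuple(TrinucleotideChannel.from_index(i) for i in range(N_CHANNELS))
CHANNEL_LABELS = tuple(ch.label for ch in CHANNELS)

#: the 32 pyrimidine-centered trinucleotides, in the order they first appear as
#: channel contexts (C-centered for channels 0-47, T-centered for 48-95)
TRINUCLEOTIDES_32 = tuple(
    five + center + three for center in PYRIMIDINES for five in BASES for three in BASES
)
_TRINUC32_INDEX = {t: i for i, t in enumerate(TRINUCLEOTIDES_32)}


def trinucleotide32_index(trinuc: str) -> int:
    """Index in 0..31 of a reference trinucleotide after pyrimidine
    normalization; raises ValueError on ambiguous (N-containing) input."""
    trinuc = trinuc.upper()
    if len(trinuc) != 3:
        raise ValueError(f"not a trinucleotide: {trinuc!r}")
    if trinuc[1] not in PYRIMIDINES:
        trinuc = revcomp(trinuc)
    idx = _TRINUC32_INDEX.get(trinuc)
    if idx is None:
        raise ValueError(f"ambiguous or invalid trinucleotide: {trinuc!r}")
    return idx


#: per-channel index into TRINUCLEOTIDES_32 (each context hosts 3 channels)
CHANNEL_TO_TRINUC32 = tuple(trinucleotide32_index(ch.trinucleotide) for ch in CHANNELS)
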