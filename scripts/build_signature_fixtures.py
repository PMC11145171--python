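"""Regenerate the bundled synthetic signature matrix.

The bundled profiles are deterministic synthetic stand-ins (not published
reference vectors) that encode the documented qualitative structure of each
mutational process:

* SBS1  — deamination of 5-methylcytosine: C>T concentrated at N[C>T]G.
* SBS5  — flat clock-like spectrum, broad with T>C and C>T tilt.
* SBS40 — flat clock-like spectrum, broad with C>A tilt (partially collinear
          with SBS5, as the real pair is).
* SBS31 — platinum adducts: C>T dominated, maxima at C[C>T]T and C[C>T]C,
          5'C-enriched, with a minor C>A and T>A component.
* SBS35 — platinum, broader: substantial C>A plus C>T (same C[C>T]T/C[C>T]C
          peaks, lower), minor T>A.

Run from the repository root:  python scripts/build_signature_fixtures.py
"""

from pathlib import Path

import numpy as np

import sys

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from chemotrace.channels import BASES, CHANNEL_LABELS, SUBSTITUTIONS  # noqa: E402

OUT = Path(__file__).resolve().parents[1] / "src" / "chemotrace" / "data" / "sbs96_synthetic_v1.tsv"


def idx(sub: str, five: str, three: str) -> int:
    return 16 * SUBSTITUTIONS.index(sub) + 4 * BASES.index(five) + BASES.index(three)


def class_slice(sub: str) -> slice:
    s = 16 * SUBSTITUTIONS.index(sub)
    return slice(s, s + 16)


def build() -> dict[str, np.ndarray]:
    rng = np.random.default_rng(20240603)
    sigs: dict[str, np.ndarray] = {}

    # SBS1: bulk at the four N[C>T]G channels
    w = np.full(96, 0.12) * rng.gamma(3.0, 1.0 / 3.0, 96)
    for five, peak in zip("ACGT", (21.0, 13.0, 24.0, 27.0)):
        w[idx("C>T", five, "G")] = peak
    sigs["SBS1"] = w / w.sum()

    # SBS5: broad, T>C / C>T tilted
    tilt = {"C>A": 0.8, "C>G": 0.55, "C>T": 1.3, "T>A": 0.6, "T>C": 1.6, "T>G": 0.75}
    w = rng.gamma(6.0, 1.0, 96)
    for sub, t in tilt.items():
        w[class_slice(sub)] *= t
    sigs["SBS5"] = w / w.sum()

    # SBS40: broad, C>A tilted; constructed as a partial blend with SBS5 so the
    # two are realistically collinear without being degenerate
    tilt = {"C>A": 1.4, "C>G": 0.7, "C>T": 0.9, "T>A": 0.95, "T>C": 1.1, "T>G": 0.8}
    w = rng.gamma(6.0, 1.0, 96)
    for sub, t in tilt.items():
        w[class_slice(sub)] *= t
    w = 0.5 * w / w.sum() + 0.5 * sigs["SBS5"]
    sigs["SBS40"] = w / w.sum()

    # SBS31: platinum; maxima at C[C>T]T then C[C>T]C
    w = np.full(96, 0.03) * rng.gamma(3.0, 1.0 / 3.0, 96)
    w[idx("C>T", "C", "T")] = 17.0
    w[idx("C>T", "C", "C")] = 15.0
    w[idx("C>T", "C", "A")] = 5.0
    w[idx("C>T", "C", "G")] = 3.5
    w[idx("C>T", "T", "T")] = 3.0
    w[idx("C>T", "A", "C")] = 2.0
    w[idx("C>T", "A", "T")] = 2.0
    for five in "ACGT":  # minor C>A with 5'C enrichment
        for three in "ACGT":
            w[idx("C>A", five, three)] += 0.55 if five == "C" else 0.25
    for three in "ACGT":  # minor T>A
        w[idx("T>A", "C", three)] += 0.45
    sigs["SBS31"] = w / w.sum()

    # SBS35: platinum, broader C>A plus C>T; same C[C>T]T/C[C>T]C peaks, lower
    w = np.full(96, 0.12) * rng.gamma(3.0, 1.0 / 3.0, 96)
    for five in "ACGT":
        for three in "ACGT":
            w[idx("C>A", five, three)] += 2.4 if five == "C" else 1.5
            w[idx("C>T", five, three)] += 1.1 if five == "C" else 0.5
            w[idx("T>A", five, three)] += 0.55
    w[idx("C>T", "C", "T")] = 7.5
    w[idx("C>T", "C", "C")] = 6.5
    sigs["SBS35"] = w / w.sum()

    return sigs


def main() -> None:
    sigs = build()
    names = ["SBS1", "SBS5", "SBS31", "SBS35", "SBS40"]
    OUT.parent.mkdir(parents=True, exist_ok=True)
    with OUT.open("w") as fh:
        fh.write("# chemotrace synthetic SBS96 stand-in profiles, version chemotrace-synthetic-v1\n")
        fh.write("# deterministic construction: scripts/build_signature_fixtures.py\n")
        fh.write("channel\t" + "\t".join(names) + "\n")
        for c, label in enumerate(CHANNEL_LABELS):
            row = "\t".join(f"{sigs[n][c]:.8e}" for n in names)
            fh.write(f"{label}\t{row}\n")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
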