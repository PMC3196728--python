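"""Regenerate the bundled synthetic exemplar transposases.

One exemplar protein per supported IS family class, with a planted
catalytic motif (DDE triad at class-typical spacers, or HuH/Y1 for the
IS200/IS605 class) and a length mirroring typical transposases of that
class.  The output is deterministic and versioned in the repository
(src/iscensus/data/exemplars.faa); rerun only when the format changes.
"""

from pathlib import Path

import numpy as np

AA = "ARNDCQEGHILKMFPSTWYV"
FREQ = np.array([8.3, 5.5, 4.0, 5.4, 1.4, 3.9, 6.8, 7.1, 2.2, 6.0,
                 9.7, 5.8, 2.4, 3.9, 4.7, 6.6, 5.5, 1.1, 3.0, 6.9])
FREQ = FREQ / FREQ.sum()

# class -> (protein length, DDE positions or None, HuH positions or None)
CLASSES = [
    ("IS1",         230, (60, 138, 183), None),
    ("IS5",         275, (75, 160, 210), None),
    ("IS982",       274, (70, 150, 205), None),
    ("IS110",       340, (90, 175, 240), None),
    ("IS200/IS605", 147, None, (8, 9, 10, 70)),
    ("IS481",       314, (85, 165, 220), None),
    ("IS1182",      457, (110, 200, 260), None),
    ("IS6",         235, (62, 140, 190), None),
    ("Tn3",         400, (100, 190, 250), None),
    ("IS3",         300, (80, 170, 225), None),
    ("YhgA-like",   300, (78, 168, 230), None),
]


def make_protein(rng, length, dde, huh):
    aas = list("".join(rng.choice(list(AA), size=length, p=FREQ)))
    aas[0] = "M"
    if dde:
        i, j, k = dde
        aas[i], aas[j], aas[k] = "D", "D", "E"
    if huh:
        i, u, j, y = huh
        aas[i], aas[u], aas[j], aas[y] = "H", "L", "H", "Y"
    return "".join(aas)


def main():
    rng = np.random.default_rng(20110926)
    out = Path(__file__).resolve().parent.parent / "src/iscensus/data/exemplars.faa"
    out.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    for idx, (cls, length, dde, huh) in enumerate(CLASSES):
        protein = make_protein(rng, length, dde, huh)
        name = f"EX{idx + 1:02d}_{cls.replace('/', '-')}"
        meta = [f"class={cls}"]
        if dde:
            meta.append("dde=" + ",".join(map(str, dde)))
        if huh:
            meta.append("huh=" + ",".join(map(str, huh)))
        lines.append(">" + " ".join([name] + meta))
        for i in range(0, len(protein), 70):
            lines.append(protein[i : i + 70])
    out.write_text("\n".join(lines) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
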