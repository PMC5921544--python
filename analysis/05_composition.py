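"""Transitive homology: PHA <-> human through the GSO reference genome.

Composes the arm-resolved PHA->GSO map with the human->GSO stand-in map and
writes the correspondence table under results/.
"""

from pathlib import Path

from paintphylo.pipeline import composition_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = composition_table()
    with open(OUT / "correspondence.tsv", "w", encoding="utf-8") as fh:
        fh.write("pha\thsa\n")
        for row in rows:
            fh.write(f"{row['pha']}\t{row['hsa']}\n")
    for row in rows:
        print(f"PHA {row['pha']} <-> HSA {row['hsa']}")
    print(f"-> {OUT/'correspondence.tsv'}")


if __name__ == "__main__":
    main()
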