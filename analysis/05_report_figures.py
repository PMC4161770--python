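"""Render the report figures for the completed run.

Per-lineage structural proportions (2-TIR / intact-ORF), the
size-vs-divergence scatter with its regression line, LTT curves against
the constant-rate null, and the TA insertion-site bias profile.
"""
from pathlib import Path

from marinerscape.pipeline import report

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    produced = report(BASE / "run")
    for p in produced:
        print("wrote", p)


if __name__ == "__main__":
    main()
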