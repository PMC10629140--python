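"""Render the human-readable figures and tables from the analysis CSVs.

Stacked-bar level distributions per ROI, two-set overlap diagrams for the
excellent and good classes, MAE-vs-mean-CCC scatters per category, and a
mean +/- SD IQM table.
"""

from pathlib import Path

from sctradiomics.report import render_report

ROOT = Path(__file__).resolve().parents[1]


def main():
    artifacts = render_report(ROOT / "results")
    for a in artifacts:
        print(f"wrote {a}")


if __name__ == "__main__":
    main()
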