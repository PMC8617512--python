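"""The study's statistical design on the processed cohort.

Baseline equivalence t-tests, delta-to-baseline scores, reduction of TIME to
the T1/T4/T9 recovery anchors, the 2 x 3 x 3 mixed ANOVA with partial eta^2
and BIC Bayes factors on the five main variables (RD, VP, MFr, elbow AM,
shoulder AM), null-control checks (R^2, AOff, trunk) with BF01, and
Newman-Keuls post hocs on TIME.  Writes results/analysis/.

Run after 02_process_trials.py:  python analysis/03_group_statistics.py
"""
import json
from pathlib import Path

from click.testing import CliRunner

from reachkin.cli import main

ROOT = Path(__file__).resolve().parents[1]
DERIVED = ROOT / "scratch" / "derived"
OUT = ROOT / "results" / "analysis"


def run() -> None:
    runner = CliRunner()
    result = runner.invoke(main, [
        "analyze", "--features", str(DERIVED / "features.csv"),
        "--lfm", str(DERIVED / "lfm.csv"), "--out", str(OUT)],
        catch_exceptions=False)
    print(result.output.strip())
    with open(OUT / "anova.json") as fh:
        anova = json.load(fh)
    print(f"corrected significance threshold: P < {anova['threshold']}")
    for rec in anova["effects"]:
        if rec["effect"] == "GROUP":
            star = " *" if rec["p"] < anova["threshold"] else ""
            print(f"GROUP effect on {rec['dv']}: "
                  f"F({rec['df_num']}, {rec['df_den']}) = {rec['F']:.2f}, "
                  f"p = {rec['p']:.2g}, partial eta^2 = "
                  f"{rec['partial_eta2']:.2f}, BF10 = "
                  f"{rec.get('BF', float('nan')):.3g}{star}")


if __name__ == "__main__":
    run()
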