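"""Simulate the full two-group immobilization cohort.

Generates 2 groups x 20 subjects, each recorded PRE and POST with
3 movements x 10 trials (2400 trials), and writes the raw marker CSVs plus
manifest and ground-truth effect table.  Raw marker data are bulky and go to
scratch/; the per-cohort summaries land in results/.

Run from the repository root:  python analysis/01_simulate_cohort.py
"""
from pathlib import Path

from click.testing import CliRunner

from reachkin.cli import main

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "cohort"
SEED = 2026


def run() -> None:
    runner = CliRunner()
    result = runner.invoke(main, ["simulate", "--n-per-group", "20",
                                  "--seed", str(SEED), "--out",
                                  str(COHORT_DIR), "--force"],
                           catch_exceptions=False)
    print(result.output.strip())
    n_files = len(list((COHORT_DIR / "trials").glob("*.csv")))
    print(f"cohort on disk: {n_files} trial files, seed {SEED}")
    (ROOT / "results").mkdir(exist_ok=True)
    gt = COHORT_DIR / "ground_truth.csv"
    (ROOT / "results" / "ground_truth.csv").write_text(gt.read_text())
    print("ground-truth effect schedule copied to results/ground_truth.csv")


if __name__ == "__main__":
    run()
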