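"""Render the human-readable summary of the analysis run.

Run after 03_group_statistics.py:  python analysis/05_report.py
"""
from pathlib import Path

from click.testing import CliRunner

from reachkin.cli import main

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "analysis"


def run() -> None:
    result = CliRunner().invoke(main, ["report", "--dir", str(OUT)],
                                catch_exceptions=False)
    print(result.output.strip())


if __name__ == "__main__":
    run()
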