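"""Replay the headline summary statistics from published-style class counts
through the package summarizers (same computation as scripts/acceptance.py)
and store them under ``results/acceptance.json``.
"""
from __future__ import annotations

import subprocess
import sys

from _common import REPO, RESULTS


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    subprocess.run(
        [sys.executable, str(REPO / "scripts" / "acceptance.py"),
         "--seed", "1", "--out", str(RESULTS / "acceptance.json")],
        check=True,
    )


if __name__ == "__main__":
    main()
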