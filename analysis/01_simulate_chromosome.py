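"""Simulate the full-scale synthetic chromosome (774.4 Mb, ~7,500 genes).

Writes the annotation, FPKM matrices, NTR intervals/sequences, antisense
table, similarity flags, truth labels, and generator config to
``scratch/dataset``. Deterministic for the fixed seed.
"""
from __future__ import annotations

import time

from _common import DATASET_DIR, SEED
from txatlas import pipeline
from txatlas.synthetic_data import SyntheticConfig


def main() -> None:
    t0 = time.time()
    cfg = SyntheticConfig(seed=SEED)
    paths = pipeline.simulate(cfg, DATASET_DIR)
    print(f"simulated {cfg.chrom_length / 1e6:.1f} Mb chromosome "
          f"in {time.time() - t0:.1f}s")
    for key, path in paths.items():
        print(f"  {key}: {path}")


if __name__ == "__main__":
    main()
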