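"""Shared paths and loading helpers for the numbered analysis scripts.

Every script is run from the repository root:

    python analysis/01_simulate_chromosome.py
    python analysis/02_classify_tars.py
    ...

01 writes the synthetic dataset bundle to ``scratch/dataset``; the later
scripts read it back through the package's file readers (exercising the same
I/O path a real dataset would take) and write compact result tables to
``results/``.
"""
from __future__ import annotations

import json
import sys
from pathlib import Path

from txatlas import io_formats as iof

REPO = Path(__file__).resolve().parent.parent
DATASET_DIR = REPO / "scratch" / "dataset"
RESULTS = REPO / "results"
SEED = 1


def require_dataset() -> None:
    if not (DATASET_DIR / "annotation.gff3").exists():
        sys.exit(
            f"dataset not found under {DATASET_DIR}; "
            "run analysis/01_simulate_chromosome.py first"
        )


def load_dataset() -> dict:
    """Read the simulated bundle back from disk."""
    require_dataset()
    genes = iof.read_gff3(DATASET_DIR / "annotation.gff3")
    matrix = iof.read_expression_matrix(DATASET_DIR / "fpkm.tsv")
    with open(DATASET_DIR / "truth.json") as fh:
        truth = json.load(fh)
    return {
        "genes": genes,
        "matrix": matrix,
        "truth": truth,
        "sequences": iof.read_fasta(DATASET_DIR / "ntr_sequences.fasta"),
        "antisense": iof.read_antisense_table(DATASET_DIR / "antisense.tsv"),
    }


def write_json(name: str, payload: dict) -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    path = RESULTS / name
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    print(f"wrote {path.relative_to(REPO)}")
    return path
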