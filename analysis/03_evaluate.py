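#!/usr/bin/env python
"""Score both pipeline runs against the generators' truth labels.

Reads results/run_default/ and results/run_sharing/ (from
analysis/02_detect_and_validate.py) together with the matching truth.json
files, recomputes sensitivity, false-positive rate, donor-origin accuracy,
contaminant rejection, event-count error and sharing accuracy, and writes
results/evaluation.tsv.
"""

import argparse
import json
from dataclasses import dataclass
from pathlib import Path

from xenoscan.synthetic import truth_evaluation

ROOT = Path(__file__).resolve().parents[1]


@dataclass
class RunView:
    validated_genes: set
    rejected_genes: set
    origin_by_gene: dict
    n_events: int
    sharing_by_genes: dict


def load_run(run_dir: Path) -> RunView:
    res = json.loads((run_dir / "result.json").read_text())
    sharing = {}
    for line in (run_dir / "events.tsv").read_text().splitlines():
        if line.startswith(("#", "event_id")):
            continue
        parts = line.split("\t")
        sharing[frozenset(parts[6].split(","))] = parts[4]
    return RunView(set(res["validated_genes"]), set(res["rejected_genes"]),
                   res["origin_by_gene"], res["n_events"], sharing)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--runs", type=Path, default=ROOT / "scratch")
    ap.add_argument("--results", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    rows = []
    for name in ("default", "sharing"):
        truth = json.loads((args.runs / "data" / name / "truth.json").read_text())
        metrics = truth_evaluation(load_run(args.runs / f"run_{name}"), truth)
        print(f"[{name}]")
        for k, v in metrics.items():
            print(f"  {k}: {v:.4f}")
            rows.append((name, k, v))
    args.results.mkdir(exist_ok=True)
    out = args.results / "evaluation.tsv"
    with open(out, "w") as fh:
        fh.write("scenario\tmetric\tvalue\n")
        for name, k, v in rows:
            fh.write(f"{name}\t{k}\t{v:.6f}\n")
    print(f"\nwritten: {out}")


if __name__ == "__main__":
    main()
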