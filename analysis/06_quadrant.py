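"""Classify units by their position relative to the cross-unit mean score
at the first and last year.

Persistent region effects put high-effect zones in quadrant I (above
average at both timepoints) and low-effect zones in quadrant III.
"""

from pathlib import Path

import pandas as pd

from hra.io_panel import read_partition, write_results
from hra.quadrant import classify_quadrants

IN = Path("results/analysis")
OUT = Path("results/analysis")


def main() -> None:
    scores = pd.read_csv(IN / "scores.csv", comment="#")
    partition = read_partition(IN / "inputs" / "regions.csv")
    years = sorted(scores["year"].unique())
    q = classify_quadrants(scores, years[0], years[-1])
    counts = q.counts_by_region(partition)
    write_results({"quadrant": q.frame, "quadrant_counts": counts}, OUT)

    print(f"quadrant classification {years[0]} vs {years[-1]} "
          f"(origin = {tuple(round(v, 4) for v in q.origin)}):")
    print(f"  counts: {q.counts()}")
    print(counts.to_string(index=False))
    if q.frame["tie_at_mean"].any():
        print(f"  note: {int(q.frame['tie_at_mean'].sum())} unit(s) tied at a mean")


if __name__ == "__main__":
    main()
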