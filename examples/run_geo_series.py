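"""Re-derive the core marker trio and run the published cascade on real GEO data.

This script performs the full pipeline on user-downloaded GEO Series Matrix
files for the three FOLFOX cohorts (e.g. GSE83129, GSE28702, GSE69657):

1. moderated-t DEG tables per cohort (resistant vs. sensitive),
2. the triple-intersection core — checks whether TMEM182, MCM9 (up) and
   LRRFIP1 (down) are recovered,
3. the published four-stage cascade on each cohort, with a Table-style
   Selected/Correct report per class.

No downloading is performed: supply the files yourself, each with a label
sidecar (JSON: sample accession -> resistant|sensitive) and, if the matrix
is probe-level, a two-column probe->gene TSV.

Usage:
    python examples/run_geo_series.py \
        --cohort GSE83129.txt:GSE83129.labels.json[:GSE83129.probes.tsv] \
        --cohort GSE28702.txt:GSE28702.labels.json \
        --cohort GSE69657.txt:GSE69657.labels.json
"""

from __future__ import annotations

import argparse

from radcascade import (
    apply_cascade,
    evaluate,
    extended_marker_selection,
    fit_cascade_normalization,
    moderated_t,
    primary_filter,
    published_folfox_cascade,
    read_label_map,
    read_series_matrix,
    venn_core,
)
from radcascade.io_expr import read_probe_map

CORE_UP = {"TMEM182", "MCM9"}
CORE_DOWN = {"LRRFIP1"}


def load(entry: str):
    parts = entry.split(":")
    if len(parts) not in (2, 3):
        raise SystemExit(f"--cohort expects matrix:labels[:probe_map], got {entry!r}")
    matrix_path, labels_path = parts[0], parts[1]
    probe_map = read_probe_map(parts[2]) if len(parts) == 3 else "embedded"
    return read_series_matrix(
        matrix_path, label_map=read_label_map(labels_path), probe_map=probe_map
    )


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", action="append", required=True,
                    help="matrix:labels[:probe_map], three times")
    args = ap.parse_args()
    if len(args.cohort) != 3:
        raise SystemExit("exactly three --cohort entries are required")

    cohorts = [load(e) for e in args.cohort]
    tables = [moderated_t(c) for c in cohorts]
    filters = [primary_filter(t) for t in tables]
    for entry, (up, down) in zip(args.cohort, filters):
        print(f"{entry.split(':')[0]}: {len(up)} up, {len(down)} down DEGs")

    core_up, core_down = venn_core([f[0] for f in filters], [f[1] for f in filters])
    print(f"\ntriple-intersection core: up={sorted(core_up)} down={sorted(core_down)}")
    print(f"core trio recovered: up {sorted(CORE_UP & core_up)} / {sorted(CORE_UP)}, "
          f"down {sorted(CORE_DOWN & core_down)} / {sorted(CORE_DOWN)}")

    panel = extended_marker_selection(tables)
    print(f"extended panel: {len(panel.up)} up, {len(panel.down)} down")

    cascade = published_folfox_cascade()
    for entry, cohort in zip(args.cohort, cohorts):
        name = entry.split(":")[0]
        missing = [g for g in cascade.genes if g not in cohort.gene_ids]
        if missing:
            print(f"\n{name}: cascade genes missing ({missing}); skipped")
            continue
        fitted = fit_cascade_normalization(cascade, cohort)
        rep = evaluate(apply_cascade(cohort, fitted))
        print(f"\n{name} — published cascade:")
        print(rep.to_frame().to_string(index=False))
        print(f"undetermined: {rep.undetermined}   "
              f"false-sensitive: {rep.false_sensitive}   "
              f"false-resistant: {rep.false_resistant}")


if __name__ == "__main__":
    main()
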