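"""Expression-matrix I/O: GEO Series Matrix parsing, probe collapsing, result tables.

The in-memory container is :class:`ExpressionMatrix` — a samples x genes
real matrix with per-sample response labels (``resistant`` / ``sensitive`` /
``unknown``).  Loaders always deliver a complete, finite matrix with unique
gene symbols: probes are collapsed to genes at load time and genes with any
missing value are dropped (with a warning) because all downstream math
assumes complete data.

Labels are never guessed from GEO metadata text; they ride in a sidecar
JSON/YAML mapping ``sample accession -> label`` because phenotype encoding
varies between series.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

VALID_LABELS = ("resistant", "sensitive", "unknown")

_TABLE_BEGIN = "!series_matrix_table_begin"
_TABLE_END = "!series_matrix_table_end"

#: Cell contents treated as missing (not parse errors) in a Series Matrix table.
_MISSING_TOKENS = frozenset({"", "na", "nan", "null", "none"})


class SeriesMatrixFormatError(ValueError):
    """Raised when a file does not follow the GEO Series Matrix layout."""


@dataclass
class ExpressionMatrix:
    """Samples x genes expression matrix with response labels.

    Parameters
    ----------
    sample_ids
        Opaque unique sample identifiers (e.g. GEO sample accessions).
    gene_ids
        Unique gene symbols (after probe collapse).
    values
        Real matrix of shape ``(n_samples, n_genes)``; all entries finite.
        Units are whatever the source provides (log2 intensity assumed but
        nothing downstream depends on the scale).
    labels
        One of ``resistant`` / ``sensitive`` / ``unknown`` per sample.
    """

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x genes array")
        if not self.labels:
            self.labels = ["unknown"] * len(self.sample_ids)
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene symbols")
        if len(self.labels) != len(self.sample_ids):
            raise ValueError("label vector length must equal sample count")
        bad = set(self.labels) - set(VALID_LABELS)
        if bad:
            raise ValueError(f"invalid labels: {sorted(bad)}")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite (resolve missing entries at load)")

    # -- convenience -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def expression(self, gene: str) -> np.ndarray:
        """Per-sample expression vector of one gene."""
        return self.values[:, self.gene_index(gene)]

    def subset_samples(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return ExpressionMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            gene_ids=list(self.gene_ids),
            values=self.values[idx, :],
            labels=[self.labels[i] for i in idx],
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.gene_index(g) for g in genes]
        return ExpressionMatrix(
            sample_ids=list(self.sample_ids),
            gene_ids=list(genes),
            values=self.values[:, idx],
            labels=list(self.labels),
        )

    def label_mask(self, label: str) -> np.ndarray:
        return np.array([lb == label for lb in self.labels], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        """Samples x genes DataFrame (samples as index)."""
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    def with_labels(self, label_map: Mapping[str, str]) -> "ExpressionMatrix":
        """Return a copy relabelled from ``sample id -> label`` (others unknown)."""
        labels = [label_map.get(s, "unknown") for s in self.sample_ids]
        return replace(self, labels=labels, values=self.values.copy())


# ---------------------------------------------------------------------------
# GEO Series Matrix reading/writing
# ---------------------------------------------------------------------------


def _unquote(token: str) -> str:
    token = token.strip()
    if len(token) >= 2 and token[0] == '"' and token[-1] == '"':
        token = token[1:-1]
    return token


def read_series_matrix(
    path: str | Path,
    label_map: Mapping[str, str] | None = None,
    probe_map: Mapping[str, str] | str = "embedded",
    collapse: str = "mean",
) -> ExpressionMatrix:
    """Read a GEO Series Matrix file into a gene-level :class:`ExpressionMatrix`.

    Parameters
    ----------
    path
        Path to the Series Matrix TSV: "!"-prefixed metadata lines and a
        probe x sample table delimited by ``!series_matrix_table_begin`` /
        ``!series_matrix_table_end``.
    label_map
        Mapping from sample accession to ``resistant``/``sensitive``.
        Samples absent from the map get label ``unknown``.
    probe_map
        Mapping probe id -> gene symbol, or the string ``"embedded"`` when
        the table's row identifiers already are gene symbols.  Probes mapping
        to an empty/unknown symbol are dropped.
    collapse
        Strategy for probes sharing a gene symbol: ``mean`` (default) or
        ``max-variance-probe``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    try:
        begin = next(i for i, ln in enumerate(lines) if ln.strip().lower().startswith(_TABLE_BEGIN))
    except StopIteration:
        raise SeriesMatrixFormatError(f"{path}: missing '{_TABLE_BEGIN}' delimiter") from None
    try:
        end = next(i for i, ln in enumerate(lines) if ln.strip().lower().startswith(_TABLE_END))
    except StopIteration:
        raise SeriesMatrixFormatError(f"{path}: missing '{_TABLE_END}' delimiter") from None
    table = [ln for ln in lines[begin + 1 : end] if ln.strip()]
    if len(table) < 2:
        raise SeriesMatrixFormatError(f"{path}: empty expression table")

    header = [_unquote(t) for t in table[0].split("\t")]
    sample_ids = header[1:]
    probe_ids: list[str] = []
    rows: list[list[float]] = []
    missing_probes: list[str] = []
    for r, ln in enumerate(table[1:], start=2):
        cells = [_unquote(t) for t in ln.split("\t")]
        if len(cells) != len(header):
            raise SeriesMatrixFormatError(
                f"{path}: table row {r} has {len(cells)} fields, expected {len(header)}"
            )
        probe = cells[0]
        vals: list[float] = []
        has_missing = False
        for c, cell in enumerate(cells[1:], start=2):
            if cell.lower() in _MISSING_TOKENS:
                has_missing = True
                vals.append(np.nan)
                continue
            try:
                vals.append(float(cell))
            except ValueError:
                raise SeriesMatrixFormatError(
                    f"{path}: non-numeric cell {cell!r} at table row {r}, column {c}"
                ) from None
        if has_missing:
            missing_probes.append(probe)
            continue
        probe_ids.append(probe)
        rows.append(vals)
    if missing_probes:
        warnings.warn(
            f"{path.name}: dropped {len(missing_probes)} probe row(s) with missing values",
            stacklevel=2,
        )
    if not rows:
        raise SeriesMatrixFormatError(f"{path}: no complete probe rows in table")

    probe_matrix = ExpressionMatrix(
        sample_ids=sample_ids,
        gene_ids=probe_ids,
        values=np.asarray(rows, dtype=float).T,
        labels=[(label_map or {}).get(s, "unknown") for s in sample_ids],
    )
    if probe_map == "embedded":
        mapping = {p: p for p in probe_ids}
    else:
        mapping = dict(probe_map)
    return collapse_probes(probe_matrix, mapping, method=collapse)


def write_series_matrix(
    matrix: ExpressionMatrix,
    path: str | Path,
    probe_ids: Sequence[str] | None = None,
    title: str = "radcascade export",
) -> None:
    """Write ``matrix`` in GEO Series Matrix layout (one probe per gene)."""
    path = Path(path)
    probes = list(probe_ids) if probe_ids is not None else list(matrix.gene_ids)
    if len(probes) != matrix.n_genes:
        raise ValueError("probe_ids length must equal number of genes")
    with path.open("w") as fh:
        fh.write(f'!Series_title\t"{title}"\n')
        fh.write(f"!Series_sample_id\t{len(matrix.sample_ids)}\n")
        fh.write(_TABLE_BEGIN + "\n")
        fh.write("\t".join(['"ID_REF"'] + [f'"{s}"' for s in matrix.sample_ids]) + "\n")
        for j, probe in enumerate(probes):
            row = "\t".join(repr(float(v)) for v in matrix.values[:, j])
            fh.write(f'"{probe}"\t{row}\n')
        fh.write(_TABLE_END + "\n")


# ---------------------------------------------------------------------------
# Probe -> gene collapse
# ---------------------------------------------------------------------------


def collapse_probes(
    matrix: ExpressionMatrix,
    mapping: Mapping[str, str],
    method: str = "mean",
) -> ExpressionMatrix:
    """Collapse a probe-level matrix to one row of values per gene symbol.

    ``mean`` averages the probe rows of a gene; ``max-variance-probe`` keeps
    the single probe with the largest variance across samples (first probe in
    input order wins ties).  Probes absent from ``mapping`` or mapped to an
    empty symbol are dropped, mirroring the removal of unknown/unnamed
    sequences upstream of marker selection.
    """
    if method not in ("mean", "max-variance-probe"):
        raise ValueError(f"unknown collapse method {method!r}")
    gene_probes: dict[str, list[int]] = {}
    order: list[str] = []
    for j, probe in enumerate(matrix.gene_ids):
        gene = mapping.get(probe, "")
        if not gene or not str(gene).strip():
            continue
        gene = str(gene).strip()
        if gene not in gene_probes:
            gene_probes[gene] = []
            order.append(gene)
        gene_probes[gene].append(j)
    if not order:
        raise ValueError("all probes unmapped: collapse would produce an empty matrix")

    cols = np.empty((matrix.n_samples, len(order)))
    for g, gene in enumerate(order):
        idx = gene_probes[gene]
        block = matrix.values[:, idx]
        if len(idx) == 1 or method == "mean":
            cols[:, g] = block.mean(axis=1)
        else:  # max-variance-probe
            variances = block.var(axis=0)
            cols[:, g] = block[:, int(np.argmax(variances))]
    return ExpressionMatrix(
        sample_ids=list(matrix.sample_ids),
        gene_ids=order,
        values=cols,
        labels=list(matrix.labels),
    )


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------


def write_result_table(result, path: str | Path) -> None:
    """Write a cascade result as TSV: sample_id, true_label, call, decided_at_step.

    Undetermined samples get an empty ``decided_at_step`` field.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample_id\ttrue_label\tcall\tdecided_at_step\n")
        for sid, lab, call, step in zip(
            result.sample_ids, result.true_labels, result.calls, result.decided_at_step
        ):
            step_s = "" if step is None else str(step)
            fh.write(f"{sid}\t{lab}\t{call}\t{step_s}\n")


def read_result_table(path: str | Path):
    """Inverse of :func:`write_result_table`."""
    from .cascade import CascadeResult  # deferred: avoids an import cycle

    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, keep_default_na=False)
    steps = [int(s) if str(s).strip() else None for s in df["decided_at_step"]]
    return CascadeResult(
        sample_ids=list(df["sample_id"]),
        calls=list(df["call"]),
        decided_at_step=steps,
        true_labels=list(df["true_label"]),
    )


# ---------------------------------------------------------------------------
# Sidecar files: label maps, panels, probe maps
# ---------------------------------------------------------------------------


def _load_structured(path: Path):
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def read_label_map(path: str | Path) -> dict[str, str]:
    """Read a JSON/YAML ``sample -> label`` sidecar; validates label values."""
    data = _load_structured(Path(path))
    if not isinstance(data, dict):
        raise ValueError(f"{path}: label map must be a mapping sample -> label")
    out = {str(k): str(v) for k, v in data.items()}
    bad = set(out.values()) - set(VALID_LABELS)
    if bad:
        raise ValueError(f"{path}: invalid labels {sorted(bad)}")
    return out


def write_label_map(labels: Mapping[str, str], path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(dict(labels), sort_keys=True))
    else:
        path.write_text(json.dumps(dict(labels), indent=1, sort_keys=True) + "\n")


def read_panel(path: str | Path):
    """Read a marker panel file ``{"up": [...], "down": [...]}`` (JSON/YAML)."""
    from .deg_stats import MarkerPanel  # deferred: avoids an import cycle

    data = _load_structured(Path(path))
    return MarkerPanel(up=list(data.get("up", [])), down=list(data.get("down", [])))


def write_panel(panel, path: str | Path) -> None:
    path = Path(path)
    data = {"up": list(panel.up), "down": list(panel.down)}
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=1) + "\n")


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV ``probe<TAB>gene`` -> dict (header line optional)."""
    out: dict[str, str] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}: probe map lines need two tab-separated columns")
        if parts[0].lower() in ("probe", "id", "id_ref") and not out:
            continue
        out[parts[0]] = parts[1]
    return out
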