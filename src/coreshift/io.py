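"""Readers/writers for the tabular and tree formats the pipeline touches.

The universal substrate is :class:`OtuTable` — an integer count matrix
(OTUs x samples) with optional per-OTU taxonomy lineages and per-sample
metadata (treatment, compartment).  Formats handled: OTU-table TSV
(taxonomy as a final ``taxonomy`` column), BIOM-JSON (dense or sparse),
metadata TSV, newick trees (via scikit-bio), square labelled
distance-matrix TSV, and edge-list TSV.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

#: lineage substrings marking host-organelle OTUs (case-insensitive)
DEFAULT_ORGANELLE_PATTERNS = ("chloroplast", "mitochondria")


class ParseError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class OtuTable:
    """Integer count matrix over OTUs (rows) and samples (columns).

    Parameters
    ----------
    counts
        Nonnegative integer matrix, shape ``(n_otus, n_samples)``.
    otu_ids, sample_ids
        Unique identifier lists matching the matrix dimensions.
    taxonomy
        Optional map OTU id -> semicolon-delimited ranked lineage string.
    metadata
        Optional map sample id -> dict with at least ``treatment`` and
        ``compartment`` keys.
    """

    counts: np.ndarray
    otu_ids: list[str]
    sample_ids: list[str]
    taxonomy: dict[str, str] = field(default_factory=dict)
    metadata: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValueError("duplicate OTU ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if self.metadata:
            missing = [s for s in self.sample_ids if s not in self.metadata]
            if missing:
                raise ValueError(f"samples missing metadata: {missing}")

    # -- basic views -------------------------------------------------

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> np.ndarray:
        """Column-normalized fractions (OTUs x samples)."""
        totals = self.counts.sum(axis=0).astype(float)
        if np.any(totals == 0):
            raise ValueError("cannot normalize a sample with zero total")
        return self.counts / totals

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    def treatments(self) -> dict[str, list[str]]:
        """Map treatment label -> sample ids, in table column order."""
        if not self.metadata:
            raise ValueError("table has no sample metadata")
        out: dict[str, list[str]] = {}
        for s in self.sample_ids:
            out.setdefault(self.metadata[s]["treatment"], []).append(s)
        return out

    def select_samples(self, sample_ids: list[str]) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        meta = {s: self.metadata[s] for s in sample_ids} if self.metadata else {}
        return OtuTable(self.counts[:, idx], list(self.otu_ids), list(sample_ids),
                        dict(self.taxonomy), meta)

    def select_otus(self, otu_ids: list[str]) -> "OtuTable":
        idx = [self.otu_ids.index(o) for o in otu_ids]
        tax = {o: self.taxonomy[o] for o in otu_ids if o in self.taxonomy}
        return OtuTable(self.counts[idx, :], list(otu_ids), list(self.sample_ids),
                        tax, dict(self.metadata))


# ---------------------------------------------------------------------------
# OTU table TSV


def write_otu_table(table: OtuTable, path) -> None:
    """TSV: first column ``#OTU_ID``, sample columns, final ``taxonomy`` column."""
    with open(path, "w", encoding="utf-8") as fh:
        cols = ["#OTU_ID", *table.sample_ids]
        if table.taxonomy:
            cols.append("taxonomy")
        fh.write("\t".join(cols) + "\n")
        for i, otu in enumerate(table.otu_ids):
            row = [otu, *(str(int(c)) for c in table.counts[i])]
            if table.taxonomy:
                row.append(table.taxonomy.get(otu, ""))
            fh.write("\t".join(row) + "\n")


def read_otu_table(path, format: str = "tsv") -> OtuTable:
    """Read an OTU table from ``tsv`` or ``biom-json``."""
    if format == "tsv":
        return _read_otu_tsv(path)
    if format == "biom-json":
        return _read_biom_json(path)
    raise ValueError(f"unknown format {format!r}")


def _read_otu_tsv(path) -> OtuTable:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or len(header) < 2:
            raise ParseError(f"{path}: header must hold an id column and samples")
        has_tax = header[-1] == "taxonomy"
        sample_ids = header[1:-1] if has_tax else header[1:]
        otu_ids: list[str] = []
        rows: list[list[int]] = []
        taxonomy: dict[str, str] = {}
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(f"{path}:{lineno}: expected {len(header)} fields, "
                                 f"got {len(parts)}")
            otu = parts[0]
            cells = parts[1:-1] if has_tax else parts[1:]
            row = []
            for j, cell in enumerate(cells):
                try:
                    val = int(cell)
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: non-integer count {cell!r} in column "
                        f"{sample_ids[j]!r}") from exc
                if val < 0:
                    raise ParseError(
                        f"{path}:{lineno}: negative count {val} in column "
                        f"{sample_ids[j]!r}")
                row.append(val)
            if otu in taxonomy or otu in otu_ids:
                raise ParseError(f"{path}:{lineno}: duplicate OTU id {otu!r}")
            otu_ids.append(otu)
            rows.append(row)
            if has_tax:
                taxonomy[otu] = parts[-1]
    return OtuTable(np.array(rows, dtype=np.int64).reshape(len(otu_ids), len(sample_ids)),
                    otu_ids, sample_ids, taxonomy)


# ---------------------------------------------------------------------------
# BIOM-JSON


def _read_biom_json(path) -> OtuTable:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    try:
        n_rows, n_cols = doc["shape"]
        otu_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        counts = np.zeros((n_rows, n_cols), dtype=np.int64)
        if doc["matrix_type"] == "dense":
            counts[:] = np.asarray(doc["data"], dtype=np.int64)
        elif doc["matrix_type"] == "sparse":
            for i, j, v in doc["data"]:
                counts[int(i), int(j)] = int(v)
        else:
            raise ParseError(f"{path}: unsupported matrix_type "
                             f"{doc['matrix_type']!r}")
        taxonomy = {}
        for r in doc["rows"]:
            md = r.get("metadata") or {}
            if md.get("taxonomy"):
                tax = md["taxonomy"]
                taxonomy[r["id"]] = "; ".join(tax) if isinstance(tax, list) else tax
    except (KeyError, TypeError) as exc:
        raise ParseError(f"{path}: malformed BIOM-JSON ({exc})") from exc
    return OtuTable(counts, otu_ids, sample_ids, taxonomy)


def write_biom_json(table: OtuTable, path, sparse: bool = True) -> None:
    if sparse:
        nz = np.nonzero(table.counts)
        data = [[int(i), int(j), int(table.counts[i, j])] for i, j in zip(*nz)]
        mtype = "sparse"
    else:
        data = table.counts.astype(int).tolist()
        mtype = "dense"
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "coreshift",
        "matrix_type": mtype,
        "matrix_element_type": "int",
        "shape": [table.n_otus, table.n_samples],
        "rows": [{"id": o,
                  "metadata": ({"taxonomy": [p.strip() for p in
                                             table.taxonomy[o].split(";")]}
                               if o in table.taxonomy else None)}
                 for o in table.otu_ids],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": data,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# metadata TSV


def write_metadata(table: OtuTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample\ttreatment\tcompartment\n")
        for s in table.sample_ids:
            md = table.metadata.get(s, {})
            fh.write(f"{s}\t{md.get('treatment', '')}\t{md.get('compartment', '')}\n")


def read_metadata(path) -> dict[str, dict[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in df.columns:
        raise ParseError(f"{path}: metadata needs a 'sample' column")
    return {row["sample"]: {"treatment": row.get("treatment", ""),
                            "compartment": row.get("compartment", "")}
            for _, row in df.iterrows()}


def attach_metadata(table: OtuTable, metadata: dict[str, dict[str, str]]) -> OtuTable:
    return OtuTable(table.counts, table.otu_ids, table.sample_ids,
                    table.taxonomy, {s: metadata[s] for s in table.sample_ids})


# ---------------------------------------------------------------------------
# newick


def read_newick(path) -> TreeNode:
    """Read a rooted newick tree; missing branch lengths become 0 (warned)."""
    tree = TreeNode.read(str(path), format="newick")
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
    if n_missing:
        warnings.warn(f"{n_missing} branches had no length; set to 0", stacklevel=2)
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# distance matrix / edge list TSV


def write_distance_matrix(labels: list[str], values: np.ndarray, path) -> None:
    pd.DataFrame(values, index=labels, columns=labels).to_csv(path, sep="\t")


def read_distance_matrix(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return list(df.index), df.to_numpy(dtype=float)


def write_edge_list(edges: pd.DataFrame, path) -> None:
    """Edge list TSV with columns otu_a, otu_b, rho, p (extra columns kept)."""
    edges.to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# organelle filter


def filter_organelle_otus(table: OtuTable,
                          patterns: tuple[str, ...] = DEFAULT_ORGANELLE_PATTERNS,
                          ) -> OtuTable:
    """Drop OTUs whose lineage contains any pattern (case-insensitive substring).

    Removes host-plastid and mitochondrial reads that pass 16S amplification;
    the sample set is unchanged and surviving counts are untouched.
    """
    if not table.taxonomy:
        raise ValueError("table has no taxonomy; cannot filter organelles")
    lowered = tuple(p.lower() for p in patterns)
    keep = [o for o in table.otu_ids
            if not any(p in table.taxonomy.get(o, "").lower() for p in lowered)]
    if not keep:
        warnings.warn("organelle filter removed every OTU", stacklevel=2)
        return OtuTable(np.zeros((0, table.n_samples), dtype=np.int64), [],
                        list(table.sample_ids), {}, dict(table.metadata))
    if len(keep) < table.n_otus:
        logger.info("organelle filter removed %d OTUs", table.n_otus - len(keep))
    return table.select_otus(keep)
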