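"""Readers, writers and validated containers for every file the pipeline touches.

Expression data arrive as linear-scale, positive normalized signals (the
output of MAS5-style array normalization); all log transforms happen inside
the analysis stages.  Gene-set annotations use the GMT exchange format,
interaction catalogs use SIF, qPCR cycle-threshold tables use CSV.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """An input violates a structural invariant of its container."""


class ParseError(ValueError):
    """A file could not be parsed; the message carries the line number."""


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Probes x samples of positive, linear-scale normalized signals.

    ``signals`` is indexed by probe id with sample ids as columns.
    ``condition_order`` is the ordered list of condition labels; the first
    entry is the reference condition against which all ratios are anchored.
    """

    signals: pd.DataFrame
    condition_of_sample: dict[str, str]
    condition_order: list[str]
    replicate_of_sample: dict[str, int]

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        if self.signals.index.duplicated().any():
            dup = self.signals.index[self.signals.index.duplicated()][0]
            raise ValidationError(f"duplicate probe id {dup!r}")
        if self.signals.columns.duplicated().any():
            dup = self.signals.columns[self.signals.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        for s in self.signals.columns:
            if s not in self.condition_of_sample:
                raise ValidationError(f"sample {s!r} missing from sample sheet")
            if self.condition_of_sample[s] not in self.condition_order:
                raise ValidationError(
                    f"sample {s!r} has condition {self.condition_of_sample[s]!r} "
                    f"not in condition order {self.condition_order}"
                )
        if len(self.condition_order) < 2:
            raise ValidationError("need at least 2 conditions")
        for cond in self.condition_order:
            n = sum(
                1
                for s in self.signals.columns
                if self.condition_of_sample[s] == cond
            )
            if n < 2:
                raise ValidationError(
                    f"condition {cond!r} has {n} replicate(s); need >= 2"
                )
        vals = self.signals.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            i, j = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"non-finite signal at probe {self.signals.index[i]!r}, "
                f"sample {self.signals.columns[j]!r}"
            )
        if np.any(vals <= 0):
            i, j = np.argwhere(vals <= 0)[0]
            raise ValidationError(
                f"non-positive signal at probe {self.signals.index[i]!r}, "
                f"sample {self.signals.columns[j]!r}"
            )

    # -- conveniences -------------------------------------------------------

    @property
    def probe_ids(self) -> list[str]:
        return list(self.signals.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.signals.columns)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_order)

    def samples_of(self, condition: str) -> list[str]:
        return [
            s
            for s in self.signals.columns
            if self.condition_of_sample[s] == condition
        ]

    def log2(self) -> pd.DataFrame:
        """Log2-transformed signal matrix (defined because signals > 0)."""
        return np.log2(self.signals)

    def residual_df(self) -> int:
        """Within-condition degrees of freedom, common to all probes."""
        return len(self.sample_ids) - self.n_conditions

    def sample_sheet(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "condition": [self.condition_of_sample[s] for s in self.sample_ids],
                "replicate": [self.replicate_of_sample[s] for s in self.sample_ids],
            }
        )


def read_expression_matrix(path: str | Path, sample_sheet_path: str | Path) -> ExpressionMatrix:
    """Read a tab-separated probes x samples table plus its sample sheet.

    The expression file has probe ids in the first column and sample ids in
    the header.  The sample sheet is a CSV with columns ``sample_id``,
    ``condition`` and ``replicate``; condition order is taken from the order
    of first appearance in the sheet (first condition = reference).
    """
    signals = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    signals.index = signals.index.astype(str)
    signals.columns = signals.columns.astype(str)
    sheet = pd.read_csv(sample_sheet_path, dtype={"sample_id": str, "condition": str})
    required = {"sample_id", "condition", "replicate"}
    if not required.issubset(sheet.columns):
        raise ParseError(
            f"sample sheet missing columns {sorted(required - set(sheet.columns))}"
        )
    sheet_samples = set(sheet["sample_id"])
    matrix_samples = set(signals.columns)
    if sheet_samples != matrix_samples:
        missing = sorted(matrix_samples - sheet_samples)
        extra = sorted(sheet_samples - matrix_samples)
        parts = []
        if missing:
            parts.append(f"samples missing from sheet: {missing}")
        if extra:
            parts.append(f"sheet samples absent from matrix: {extra}")
        raise ValidationError("; ".join(parts))
    cond_order: list[str] = []
    for c in sheet["condition"]:
        if c not in cond_order:
            cond_order.append(c)
    return ExpressionMatrix(
        signals=signals,
        condition_of_sample=dict(zip(sheet["sample_id"], sheet["condition"])),
        condition_order=cond_order,
        replicate_of_sample=dict(
            zip(sheet["sample_id"], sheet["replicate"].astype(int))
        ),
    )


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, sample_sheet_path: str | Path
) -> None:
    """Write the expression TSV and sample sheet CSV read back by
    :func:`read_expression_matrix`."""
    out = matrix.signals.copy()
    out.index.name = "probe_id"
    # %.17g round-trips every IEEE double exactly
    out.to_csv(path, sep="\t", float_format="%.17g")
    matrix.sample_sheet().to_csv(sample_sheet_path, index=False)


# ---------------------------------------------------------------------------
# gene-set annotations (GMT)
# ---------------------------------------------------------------------------


@dataclass
class AnnotationSet:
    """Named gene-set catalog for one namespace (e.g. GO-BP or KEGG)."""

    namespace: str
    categories: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for cid, (_, genes) in self.categories.items():
            if not genes:
                raise ValidationError(f"category {cid!r} has an empty gene set")

    def genes_of(self, category_id: str) -> frozenset[str]:
        return self.categories[category_id][1]

    def __len__(self) -> int:
        return len(self.categories)


def read_gmt(path: str | Path, namespace: str) -> AnnotationSet:
    """Parse a GMT file: one category per line, ``name TAB description TAB
    gene TAB gene ...``."""
    categories: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected name, description and at "
                    f"least one gene, got {len(fields)} field(s)"
                )
            name, desc = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ParseError(f"{path}: line {lineno}: category {name!r} has no genes")
            if name in categories:
                raise ParseError(f"{path}: line {lineno}: duplicate category {name!r}")
            categories[name] = (desc, genes)
    return AnnotationSet(namespace=namespace, categories=categories)


def write_gmt(annotations: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cid, (desc, genes) in annotations.categories.items():
            fh.write("\t".join([cid, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# interaction catalog (SIF)
# ---------------------------------------------------------------------------


@dataclass
class InteractionCatalog:
    """Directed, typed gene-gene relations (source, relation type, target)."""

    relations: list[tuple[str, str, str]] = field(default_factory=list)
    allow_self: bool = False

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        unique: list[tuple[str, str, str]] = []
        for rel in self.relations:
            src, kind, dst = rel
            if src == dst and not self.allow_self:
                raise ValidationError(f"self-relation on {src!r} not allowed")
            if rel not in seen:
                seen.add(rel)
                unique.append(rel)
        self.relations = unique

    def __len__(self) -> int:
        return len(self.relations)

    def pairs(self) -> set[tuple[str, str]]:
        """Directed (source, target) pairs irrespective of relation type."""
        return {(s, t) for s, _, t in self.relations}


def read_sif(path: str | Path, allow_self: bool = False) -> InteractionCatalog:
    """Parse SIF: ``source TAB relation TAB target [TAB target ...]``;
    multi-target lines expand to one relation per target."""
    relations: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected source, relation, target"
                )
            src, kind = fields[0], fields[1]
            for dst in fields[2:]:
                if not dst:
                    raise ParseError(f"{path}: line {lineno}: empty target field")
                relations.append((src, kind, dst))
    return InteractionCatalog(relations=relations, allow_self=allow_self)


def write_sif(catalog: InteractionCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for src, kind, dst in catalog.relations:
            fh.write(f"{src}\t{kind}\t{dst}\n")


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------

QPCR_COLUMNS = ["gene", "condition", "bio_rep", "tech_rep", "ct"]


@dataclass
class QpcrPlate:
    """Long-format cycle-threshold table plus the reference (housekeeping) gene.

    One row per well: gene, condition, biological replicate, technical
    replicate, Ct.  The reference gene must be measured in every
    (condition, biological replicate) block so that dCt is always defined.
    """

    wells: pd.DataFrame
    reference_gene: str

    def __post_init__(self) -> None:
        missing = [c for c in QPCR_COLUMNS if c not in self.wells.columns]
        if missing:
            raise ValidationError(f"qPCR table missing columns {missing}")
        ct = self.wells["ct"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ct)):
            raise ValidationError("non-finite Ct value")
        if np.any(ct < 0) or np.any(ct > 45):
            bad = self.wells.loc[(ct < 0) | (ct > 45)].iloc[0]
            raise ValidationError(
                f"Ct {bad['ct']} out of range [0, 45] for gene {bad['gene']!r}"
            )
        blocks = self.wells.groupby(["condition", "bio_rep"])["gene"].apply(set)
        for (cond, rep), genes in blocks.items():
            if self.reference_gene not in genes:
                raise ValidationError(
                    f"reference gene {self.reference_gene!r} missing from block "
                    f"(condition={cond!r}, bio_rep={rep})"
                )

    @property
    def genes(self) -> list[str]:
        return sorted(self.wells["gene"].unique())


def read_qpcr_csv(path: str | Path, reference_gene: str) -> QpcrPlate:
    wells = pd.read_csv(path, dtype={"gene": str, "condition": str},
                        float_precision="round_trip")
    return QpcrPlate(wells=wells, reference_gene=reference_gene)


def write_qpcr_csv(plate: QpcrPlate, path: str | Path) -> None:
    plate.wells[QPCR_COLUMNS].to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# stage result tables and run manifests
# ---------------------------------------------------------------------------


def write_results_tables(
    results: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    parameters: Mapping[str, object] | None = None,
    seed: int | None = None,
) -> dict[str, str]:
    """Write each result table as a TSV with stable column order and a JSON
    run manifest recording parameters, seed and file checksums.

    Returns a map from table name to file path.  Identical inputs produce
    byte-identical files (floats are formatted, not repr'd).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    checksums: dict[str, str] = {}
    for name, table in results.items():
        path = out / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False, float_format="%.10g")
        written[name] = str(path)
        checksums[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = {
        "parameters": _jsonable(parameters or {}),
        "seed": seed,
        "tables": {name: {"path": written[name], "sha256": checksums[name]} for name in written},
        "package": "co2prof",
        "version": _package_version(),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written["manifest"] = str(manifest_path)
    return written


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("co2prof")
    except Exception:
        return "unknown"


def _jsonable(obj: object) -> object:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj
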