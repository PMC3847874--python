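"""Readers and writers for the on-disk artifacts.

All formats are plain tab-separated text:

* expression: header row of sample ids (first cell ignored), one feature per
  row;
* signature: ``gene<TAB>risk_class[<TAB>ordering_value]``;
* survival: ``sample<TAB>time_months<TAB>event``;
* labels: ``sample<TAB>group``;
* network: ``regulator<TAB>target<TAB>mi<TAB>support<TAB>mode<TAB>rho``
  (mode/rho optional on read, written as ``NA`` when unannotated).

Floats are serialized in scientific notation with 12 significant digits so a
write/read round trip is an identity at test tolerance.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    MODES,
    UNDETERMINED,
    ConsensusNetwork,
    ExpressionMatrix,
    GroupLabels,
    NetworkEdge,
    ProbeGeneMap,
    PrognetError,
    Signature,
    SurvivalTable,
)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.12e"


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


# ---------------------------------------------------------------- expression

def read_expression_matrix(path: str | Path, cohort_label: str = "") -> ExpressionMatrix:
    """Read a tab-separated log2 expression matrix (features x samples)."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise PrognetError(f"{path}: empty expression file")
        sample_ids = header.split("\t")[1:]
        rows: list[np.ndarray] = []
        feature_ids: list[str] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(sample_ids) + 1:
                raise PrognetError(
                    f"{path}:{lineno}: ragged row ({len(cells) - 1} values, "
                    f"expected {len(sample_ids)})"
                )
            feature_ids.append(cells[0])
            try:
                rows.append(np.array([float(c) for c in cells[1:]]))
            except ValueError:
                bad = next(i for i, c in enumerate(cells[1:]) if not _is_float(c))
                raise PrognetError(
                    f"{path}:{lineno}: non-numeric cell for feature {cells[0]!r}, "
                    f"sample {sample_ids[bad]!r}: {cells[1 + bad]!r}"
                ) from None
    if not feature_ids:
        raise PrognetError(f"{path}: no feature rows")
    data = pd.DataFrame(np.vstack(rows), index=feature_ids, columns=sample_ids)
    return ExpressionMatrix(data, cohort_label=cohort_label or path.stem)


def _is_float(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("feature\t" + "\t".join(expr.sample_ids) + "\n")
        for feature, row in zip(expr.feature_ids, expr.data.to_numpy()):
            fh.write(feature + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


# ----------------------------------------------------------------- signature

def read_signature(path: str | Path) -> Signature:
    """Read a gene/risk-class table, with optional ordering values."""
    path = Path(path)
    entries: list[tuple[str, str]] = []
    ordering: dict[str, float] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if lineno == 1 and cells[0].lower() in ("gene", "gene_id"):
                continue
            if len(cells) not in (2, 3):
                raise PrognetError(f"{path}:{lineno}: expected 2 or 3 columns")
            gene, risk = cells[0], cells[1]
            entries.append((gene, risk))
            if len(cells) == 3:
                ordering[gene] = float(cells[2])
    if not entries:
        raise PrognetError(f"{path}: no signature entries")
    return Signature(entries, ordering)


def write_signature(sig: Signature, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene\trisk_class\tordering_value\n")
        for gene, risk in sig.entries:
            ov = sig.ordering_value.get(gene)
            fh.write(f"{gene}\t{risk}\t{_fmt(ov) if ov is not None else 'NA'}\n")


# ------------------------------------------------------------------ survival

def read_survival(path: str | Path) -> SurvivalTable:
    path = Path(path)
    records: list[tuple[str, float, int]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if lineno == 1 and cells[0].lower() in ("sample", "sample_id"):
                continue
            if len(cells) != 3:
                raise PrognetError(f"{path}:{lineno}: expected 3 columns")
            sample, time_s, event_s = cells
            event = int(event_s)
            records.append((sample, float(time_s), event))
    return SurvivalTable(records)


def write_survival(surv: SurvivalTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample\ttime\tevent\n")
        for sample, time, event in surv.records:
            fh.write(f"{sample}\t{_fmt(time)}\t{event}\n")


# -------------------------------------------------------------------- labels

def read_labels(path: str | Path) -> GroupLabels:
    path = Path(path)
    assignments: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if lineno == 1 and cells[0].lower() in ("sample", "sample_id"):
                continue
            if len(cells) != 2:
                raise PrognetError(f"{path}:{lineno}: expected 2 columns")
            if cells[0] in assignments:
                raise PrognetError(f"{path}:{lineno}: duplicate sample {cells[0]!r}")
            assignments[cells[0]] = cells[1]
    return GroupLabels(assignments)


def write_labels(labels: GroupLabels, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample\tgroup\n")
        for sample, group in labels.assignments.items():
            fh.write(f"{sample}\t{group}\n")


# ------------------------------------------------------------- probe mapping

def read_probe_map(path: str | Path) -> ProbeGeneMap:
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if lineno == 1 and cells[0].lower() in ("probe", "probe_id"):
                continue
            if len(cells) != 2:
                raise PrognetError(f"{path}:{lineno}: expected 2 columns")
            pairs.append((cells[0], cells[1]))
    return ProbeGeneMap(pairs)


def write_probe_map(pmap: ProbeGeneMap, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("probe\tgene\n")
        for probe, gene in pmap.pairs:
            fh.write(f"{probe}\t{gene}\n")


# ------------------------------------------------------------------- network

def read_network(path: str | Path) -> ConsensusNetwork:
    path = Path(path)
    edges: list[NetworkEdge] = []
    B = 1
    level = "gene"
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                meta = line[1:].strip().split("=")
                if len(meta) == 2 and meta[0].strip() == "B":
                    B = int(meta[1])
                if len(meta) == 2 and meta[0].strip() == "level":
                    level = meta[1].strip()
                continue
            cells = line.split("\t")
            if cells[0] == "regulator":
                continue
            if len(cells) not in (4, 6):
                raise PrognetError(f"{path}:{lineno}: expected 4 or 6 columns")
            mode = None
            rho = None
            if len(cells) == 6:
                mode = None if cells[4] == "NA" else cells[4]
                if mode is not None and mode not in (*MODES, UNDETERMINED):
                    raise PrognetError(f"{path}:{lineno}: unknown mode token {mode!r}")
                rho = None if cells[5] == "NA" else float(cells[5])
            edges.append(
                NetworkEdge(cells[0], cells[1], float(cells[2]), int(cells[3]), mode, rho)
            )
    return ConsensusNetwork(edges, B=B, level=level)


def write_network(net: ConsensusNetwork, path: str | Path) -> None:
    """Write an edge list sorted by (regulator, descending MI)."""
    ordered = sorted(net.edges, key=lambda e: (e.regulator, -e.mi, e.target))
    with Path(path).open("w") as fh:
        fh.write(f"# B={net.B}\n# level={net.level}\n")
        fh.write("regulator\ttarget\tmi\tsupport\tmode\trho\n")
        for e in ordered:
            mode = e.mode if e.mode is not None else "NA"
            rho = _fmt(e.rho) if e.rho is not None else "NA"
            fh.write(f"{e.regulator}\t{e.target}\t{_fmt(e.mi)}\t{e.support}\t{mode}\t{rho}\n")


# ------------------------------------------------------------ table exports

def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write any result table as TSV with the package float convention."""
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# ------------------------------------------------------------- group ratios

def log2_group_ratio(expr: ExpressionMatrix, labels: GroupLabels, gene: str) -> float:
    """Poor-vs-good log2 expression ratio for one gene.

    Inputs are already log2, so the ratio is the difference of the group
    means: mean(poor) - mean(good).
    """
    values = expr.row(gene)
    by_sample = dict(zip(expr.sample_ids, values))
    poor = [by_sample[s] for s in labels.samples_in("poor") if s in by_sample]
    good = [by_sample[s] for s in labels.samples_in("good") if s in by_sample]
    if not poor or not good:
        raise PrognetError("both prognostic groups must be non-empty")
    return float(np.mean(poor) - np.mean(good))
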