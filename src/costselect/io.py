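"""Reading and writing the package's external formats.

Feature matrices are delimited text with a header row of feature ids and
one sample per row; the binary response is either a named column of the
same file or a separate single-column file.  Costs are two-column
delimited text (feature_id, cost), header optional.  Delimiters are
auto-detected among comma/tab unless given explicitly.

Selection results are serialized as JSON, benchmark tables as tidy CSV;
every artifact carries a schema version.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .data import CostModel, Dataset, SelectionResult
from .simulate import SimulatedProblem

__all__ = [
    "SCHEMA_VERSION",
    "read_dataset",
    "read_costs",
    "write_selection",
    "read_selection",
    "write_benchmark",
    "read_benchmark",
    "export_problem",
]

SCHEMA_VERSION = "1"


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return ","


def read_dataset(
    path: str | Path,
    response_col: Optional[str] = None,
    response_path: Optional[str | Path] = None,
    delimiter: Optional[str] = None,
    role: str = "train",
) -> Dataset:
    """Load a feature matrix plus binary response.

    Exactly one of ``response_col`` (a column of the matrix file) or
    ``response_path`` (a separate one-column file) must be given.
    """
    path = Path(path)
    if (response_col is None) == (response_path is None):
        raise ValueError("give exactly one of response_col or response_path")
    sep = delimiter or _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=sep)
    if response_col is not None:
        if response_col not in frame.columns:
            raise ValueError(f"response column {response_col!r} not found in {path}")
        y = frame.pop(response_col).to_numpy()
    else:
        rpath = Path(response_path)
        rsep = delimiter or _sniff_delimiter(rpath)
        rframe = pd.read_csv(rpath, sep=rsep, header=None)
        first = rframe.iloc[0, 0]
        if isinstance(first, str) and not first.strip().lstrip("-").isdigit():
            rframe = rframe.iloc[1:]  # header line
        y = rframe.iloc[:, 0].astype(int).to_numpy()
    return Dataset(
        features=frame.to_numpy(dtype=float),
        response=y,
        feature_ids=tuple(frame.columns),
        role=role,
    )


def read_costs(
    path: str | Path, budget: float, gamma: Optional[float] = None,
    delimiter: Optional[str] = None,
) -> CostModel:
    """Load a (feature_id, cost) table into a :class:`CostModel`."""
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=sep, header=None, dtype=str)
    # tolerate an optional header line
    try:
        float(frame.iloc[0, 1])
    except (ValueError, TypeError):
        frame = frame.iloc[1:]
    if frame.shape[1] < 2:
        raise ValueError(f"cost file {path} needs two columns (feature_id, cost)")
    costs = pd.Series(
        frame.iloc[:, 1].astype(float).to_numpy(),
        index=frame.iloc[:, 0].astype(str).to_numpy(),
    )
    return CostModel(costs=costs, budget=budget, gamma=gamma)


def _jsonable(value):
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    if isinstance(value, dict):
        return {k: _jsonable(v) for k, v in value.items()}
    return value


def write_selection(result: SelectionResult, path: str | Path) -> None:
    """Serialize a selection result as JSON (schema-versioned)."""
    payload = {"schema_version": SCHEMA_VERSION}
    payload.update({k: _jsonable(v) for k, v in dataclasses.asdict(result).items()})
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_selection(path: str | Path) -> SelectionResult:
    payload = json.loads(Path(path).read_text())
    payload.pop("schema_version", None)
    payload["members"] = tuple(payload.get("members", ()))
    return SelectionResult(**payload)


def write_benchmark(table: pd.DataFrame, path: str | Path) -> None:
    """Write the tidy benchmark table as CSV with a schema comment line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# costselect benchmark schema_version={SCHEMA_VERSION}\n")
        table.to_csv(fh, index=False)


def read_benchmark(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def export_problem(problem: SimulatedProblem, out_dir: str | Path) -> dict[str, Path]:
    """Write a realized replicate as CSV files plus a metadata sidecar.

    Produces ``train.csv`` / ``test.csv`` (features + ``y`` column),
    ``costs.csv`` and ``meta.json`` (budget, gamma, relevance mask, spec).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, data in (("train", problem.train), ("test", problem.test)):
        frame = pd.DataFrame(data.features, columns=list(data.feature_ids))
        frame["y"] = data.response
        paths[name] = out / f"{name}.csv"
        frame.to_csv(paths[name], index=False)
    costs = problem.cost_model.costs
    paths["costs"] = out / "costs.csv"
    costs.rename("cost").rename_axis("feature_id").reset_index().to_csv(
        paths["costs"], index=False, header=False
    )
    meta = {
        "schema_version": SCHEMA_VERSION,
        "budget": problem.cost_model.budget,
        "gamma": problem.cost_model.gamma,
        "relevance_mask": problem.relevance_mask.astype(int).tolist(),
        "spec": problem.spec.to_dict(),
    }
    paths["meta"] = out / "meta.json"
    paths["meta"].write_text(json.dumps(meta, indent=2) + "\n")
    return paths
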