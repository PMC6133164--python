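"""Plain-text file formats for partitions, samples and run reports.

Sample files are model-agnostic: one partition per line, integer labels
separated by whitespace or commas, with an optional non-numeric header line.
Nothing about the model that produced the draws (mixture, block model, ...)
is encoded in the format.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .greedy import GreedyResult
from .losses import expected_posterior_loss
from .partitions import PartitionSample, as_partition

__all__ = [
    "read_partition_sample",
    "read_partition",
    "write_partition",
    "write_partition_sample",
    "write_result",
    "read_report",
]


class FormatError(ValueError):
    """A file does not parse as the expected plain-text format."""


def _tokenise(line: str) -> list[str]:
    return line.replace(",", " ").split()


def _is_numeric_row(tokens: list[str]) -> bool:
    try:
        for tok in tokens:
            int(tok)
    except ValueError:
        return False
    return len(tokens) > 0


def read_partition_sample(path, weights_path=None) -> PartitionSample:
    """Read a T×N label matrix (and optional per-row weights) from text files.

    One partition per line; labels separated by commas or whitespace; a
    single leading non-numeric header line is ignored.  Rows must be
    rectangular and labels positive integers.
    """
    lines = Path(path).read_text().splitlines()
    rows: list[list[int]] = []
    first_data_line = None
    for lineno, line in enumerate(lines, start=1):
        tokens = _tokenise(line)
        if not tokens:
            continue
        if not _is_numeric_row(tokens):
            if not rows and first_data_line is None:
                continue  # header
            raise FormatError(f"{path}: non-integer label on line {lineno}")
        if first_data_line is None:
            first_data_line = lineno
        row = [int(tok) for tok in tokens]
        if rows and len(row) != len(rows[0]):
            raise FormatError(
                f"{path}: line {lineno} has {len(row)} labels, expected {len(rows[0])}"
            )
        if any(v < 1 for v in row):
            raise FormatError(f"{path}: non-positive label on line {lineno}")
        rows.append(row)
    if not rows:
        raise FormatError(f"{path}: no partitions found")
    labels = np.asarray(rows, dtype=np.int64)

    weights = None
    if weights_path is not None:
        wtokens = Path(weights_path).read_text().split()
        try:
            weights = np.asarray([float(tok) for tok in wtokens])
        except ValueError:
            raise FormatError(f"{weights_path}: non-numeric weight") from None
        if weights.size != labels.shape[0]:
            raise FormatError(
                f"{weights_path}: {weights.size} weights for {labels.shape[0]} rows"
            )
        if np.any(weights <= 0):
            raise FormatError(f"{weights_path}: weights must be positive")
    return PartitionSample(labels, weights)


def read_partition(path) -> np.ndarray:
    """Read a single partition (the first data line of a sample file)."""
    sample = read_partition_sample(path)
    return sample.labels[0]


def write_partition(path, p) -> None:
    """Write one partition as a single line of space-separated labels."""
    arr = as_partition(p)
    Path(path).write_text(" ".join(str(int(v)) for v in arr) + "\n")


def write_partition_sample(path, sample: PartitionSample,
                           with_weights: bool = False) -> None:
    """Write a sample, one row per line; optionally append a weight column."""
    lines = []
    for t in range(sample.n_draws):
        row = " ".join(str(int(v)) for v in sample.labels[t])
        if with_weights:
            w = float(sample.weights[t])
            row += " " + (str(int(w)) if w.is_integer() else repr(w))
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


def write_result(path, result: GreedyResult, report_path=None) -> None:
    """Write the optimal partition, plus a key/value report alongside.

    The report records the loss name, the achieved expected posterior loss,
    the number of groups, how many restarts reached the best value, the
    per-restart sweep counts and the seed.  Re-reading the partition and
    recomputing its EPL against the input sample reproduces the reported
    value.
    """
    write_partition(path, result.partition)
    if report_path is None:
        report_path = str(path) + ".report"
    sweeps = ",".join(str(s) for s in result.sweeps_per_restart)
    lines = [
        f"loss: {result.loss_name}",
        f"epl: {float(result.epl)!r}",
        f"k: {result.k}",
        f"restarts: {len(result.sweeps_per_restart)}",
        f"restarts_hit_best: {result.n_restarts_hit_best}",
        f"sweeps_per_restart: {sweeps}",
        f"seed: {result.seed}",
    ]
    Path(report_path).write_text("\n".join(lines) + "\n")


def read_report(path) -> dict:
    """Parse a key/value report file back into a dict of strings."""
    out = {}
    for line in Path(path).read_text().splitlines():
        if ":" in line:
            key, _, val = line.partition(":")
            out[key.strip()] = val.strip()
    return out


def check_result_consistency(partition_path, sample: PartitionSample,
                             report: dict) -> float:
    """Recompute the EPL of a written partition; returns the value."""
    p = read_partition(partition_path)
    return expected_posterior_loss(p, sample, report["loss"])
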