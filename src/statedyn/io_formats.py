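"""Typed readers/writers for every table the pipeline touches.

All inputs are plain delimited text: per-subject parcellated BOLD series
(T rows x N channels, header row of channel labels), a phenotype table
(subject_id, score, sex, age, mean_fd), and a YAML map from channel label
to large-scale network name.  Validation is strict and errors name the
offending cell, so downstream modules can assume well-formed objects.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Threshold (mm) above which mean framewise displacement excludes a subject.
DEFAULT_FD_THRESHOLD = 0.2

REQUIRED_PHENOTYPE_COLUMNS = ("subject_id", "score", "sex", "age", "mean_fd")


class ValidationError(ValueError):
    """A table violated an invariant of its domain type."""


@dataclasses.dataclass
class ParcellatedTimeSeries:
    """One subject's T x N matrix of network/ROI BOLD signals.

    Rows are time (scan order preserved), columns are channels.  Units are
    arbitrary BOLD units; most downstream stages z-score per channel.
    """

    subject_id: str
    data: np.ndarray
    channel_labels: list[str]
    tr_seconds: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError(
                f"{self.subject_id}: time series must be 2-D, got {self.data.ndim}-D"
            )
        t, n = self.data.shape
        if t < 2:
            raise ValidationError(f"{self.subject_id}: need at least 2 timepoints, got {t}")
        if n < 2:
            raise ValidationError(f"{self.subject_id}: need at least 2 channels, got {n}")
        if len(self.channel_labels) != n:
            raise ValidationError(
                f"{self.subject_id}: {len(self.channel_labels)} labels for {n} columns"
            )
        if len(set(self.channel_labels)) != n:
            raise ValidationError(f"{self.subject_id}: channel labels are not unique")
        bad = np.argwhere(~np.isfinite(self.data))
        if bad.size:
            r, c = bad[0]
            raise ValidationError(
                f"{self.subject_id}: non-finite value at row {r}, "
                f"column {self.channel_labels[c]!r}"
            )
        if self.tr_seconds is not None and self.tr_seconds <= 0:
            raise ValidationError(f"{self.subject_id}: tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


class PhenotypeTable:
    """Per-subject phenotype rows: depression score plus nuisance covariates.

    Columns: ``subject_id`` (unique), ``score`` (scale units), ``sex``
    (0/1), ``age`` (years), ``mean_fd`` (mm, >= 0).  ``n_dropped_motion``
    records how many rows a motion filter removed at read time.
    """

    def __init__(self, df: pd.DataFrame, n_dropped_motion: int = 0) -> None:
        missing = [c for c in REQUIRED_PHENOTYPE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"phenotype table missing required columns: {missing}")
        df = df.copy()
        df["subject_id"] = df["subject_id"].astype(str)
        if df["subject_id"].duplicated().any():
            dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise ValidationError(f"duplicate subject_id values: {dupes}")
        for col in ("score", "age", "mean_fd"):
            df[col] = pd.to_numeric(df[col], errors="raise")
        if df[list(REQUIRED_PHENOTYPE_COLUMNS)].isna().any().any():
            col = df[list(REQUIRED_PHENOTYPE_COLUMNS)].isna().any().idxmax()
            raise ValidationError(f"missing values in required column {col!r}")
        if (df["mean_fd"] < 0).any():
            raise ValidationError("mean_fd must be non-negative")
        if not set(df["sex"].unique()) <= {0, 1}:
            raise ValidationError("sex must be coded 0/1")
        self.df = df.reset_index(drop=True)
        self.n_dropped_motion = int(n_dropped_motion)

    @property
    def subject_ids(self) -> list[str]:
        return self.df["subject_id"].tolist()

    def __len__(self) -> int:
        return len(self.df)

    def aligned(self, subject_ids: Sequence[str]) -> pd.DataFrame:
        """Rows reordered to ``subject_ids``; raises listing any unmatched IDs."""
        idx = self.df.set_index("subject_id")
        missing = [s for s in subject_ids if s not in idx.index]
        if missing:
            raise ValidationError(f"subjects missing from phenotype table: {missing}")
        return idx.loc[list(subject_ids)].reset_index()

    def covariate_matrix(self, subject_ids: Sequence[str]) -> np.ndarray:
        """Subjects x 3 matrix of (sex, age, mean_fd) covariates."""
        sub = self.aligned(subject_ids)
        return sub[["sex", "age", "mean_fd"]].to_numpy(dtype=float)

    def scores(self, subject_ids: Sequence[str]) -> np.ndarray:
        return self.aligned(subject_ids)["score"].to_numpy(dtype=float)


class NetworkMap:
    """Mapping channel label -> network name, with a fixed network order."""

    def __init__(
        self,
        channel_to_network: Mapping[str, str],
        network_order: Sequence[str] | None = None,
    ) -> None:
        self.channel_to_network = dict(channel_to_network)
        if network_order is None:
            seen: dict[str, None] = {}
            for net in self.channel_to_network.values():
                seen.setdefault(net, None)
            network_order = list(seen)
        else:
            network_order = list(network_order)
            extra = set(self.channel_to_network.values()) - set(network_order)
            if extra:
                raise ValidationError(f"networks missing from declared order: {sorted(extra)}")
        if len(network_order) < 2:
            raise ValidationError("need at least 2 networks")
        self.networks = network_order

    @property
    def n_networks(self) -> int:
        return len(self.networks)

    def channel_indices(self, channel_labels: Sequence[str]) -> dict[str, np.ndarray]:
        """Column indices per network for a given channel ordering."""
        unmapped = [c for c in channel_labels if c not in self.channel_to_network]
        if unmapped:
            raise ValidationError(f"channels not present in network map: {unmapped}")
        out: dict[str, list[int]] = {net: [] for net in self.networks}
        for i, label in enumerate(channel_labels):
            out[self.channel_to_network[label]].append(i)
        return {net: np.asarray(ix, dtype=int) for net, ix in out.items()}

    def network_pairs(self) -> list[tuple[str, str]]:
        """All M(M-1)/2 unordered network pairs, in declared network order."""
        nets = self.networks
        return [(nets[i], nets[j]) for i in range(len(nets)) for j in range(i + 1, len(nets))]


def _read_delimited(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    sep = delimiter if delimiter is not None else "\t"
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_timeseries(
    path: str | Path, subject_id: str, delimiter: str | None = None
) -> ParcellatedTimeSeries:
    """Read one subject's delimited T x N table (header = channel labels)."""
    df = _read_delimited(path, delimiter)
    labels = [str(c) for c in df.columns]
    try:
        data = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: non-numeric entry in time series ({exc})") from exc
    return ParcellatedTimeSeries(subject_id=subject_id, data=data, channel_labels=labels)


def write_timeseries(ts: ParcellatedTimeSeries, path: str | Path) -> None:
    df = pd.DataFrame(ts.data, columns=ts.channel_labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.15g")


def read_phenotypes(
    path: str | Path,
    fd_threshold: float | None = DEFAULT_FD_THRESHOLD,
    delimiter: str | None = None,
) -> PhenotypeTable:
    """Read the phenotype table, optionally dropping high-motion subjects.

    ``fd_threshold`` (mm) drops rows with ``mean_fd`` strictly above it and
    records the count in ``n_dropped_motion``; pass ``None`` to keep all rows.
    """
    df = _read_delimited(path, delimiter)
    table = PhenotypeTable(df)  # validate before filtering
    n_dropped = 0
    if fd_threshold is not None:
        keep = table.df["mean_fd"] <= fd_threshold
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info(
                "motion filter (mean FD > %.3g mm) dropped %d of %d subjects",
                fd_threshold, n_dropped, len(table.df),
            )
        table = PhenotypeTable(table.df.loc[keep], n_dropped_motion=n_dropped)
    return table


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False, float_format="%.15g")


def read_network_map(path: str | Path) -> NetworkMap:
    """Read a YAML network map.

    Accepts either a plain ``{channel: network}`` mapping or a document with
    keys ``channels`` (the mapping) and optional ``networks`` (ordered list).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValidationError(f"{path}: network map must be a YAML mapping")
    if "channels" in doc:
        return NetworkMap(doc["channels"], doc.get("networks"))
    return NetworkMap(doc)


def write_network_map(network_map: NetworkMap, path: str | Path) -> None:
    doc = {
        "networks": list(network_map.networks),
        "channels": dict(network_map.channel_to_network),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_association_table(results: Sequence, path: str | Path) -> None:
    """Write association results as TSV; floats round-trip losslessly."""
    if not results:
        raise ValidationError("refusing to write an empty association table")
    rows = [dataclasses.asdict(r) for r in results]
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_association_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    df["significant"] = df["significant"].astype(bool)
    return df
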