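"""Reading and writing compound-potency datasets and evaluation reports.

The dataset dialect is comma-separated UTF-8 text with a header row and
``#``-prefixed metadata lines declaring the dataset name, endpoint kind and
species, e.g.::

    # name = demo
    # endpoint = apd_ternary
    # species = dog
    compound_id,concentration_uM,label,IKr_mode,IKr_potency_uM,IKr_n,IKr_emax,...

One row per compound: identifier, test concentration, endpoint label, then
per channel (IKr, ICaL, INa) a mode, a potency, a Hill coefficient and an
Emax.  Empty cells mean the channel was not measured (no activity).  The
canonical unit is µM; a schema config can declare that a source file's
concentrations or potencies are in nM or mM and they are converted on load.
Censored potencies written as ``>X`` (no effect seen up to the top test
concentration) carry no usable Hill parameters and load as missing
activities, with a log note.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import classifier as _cls
from .pharmacology import Channel, ChannelActivity, Mode

logger = logging.getLogger(__name__)

__all__ = [
    "Endpoint",
    "CompoundRecord",
    "Dataset",
    "SchemaConfig",
    "DatasetLoadError",
    "read_dataset",
    "write_dataset",
    "write_report",
    "positive_label",
]


class Endpoint(str, enum.Enum):
    """Endpoint kinds mirroring the literature data-set designs."""

    TDP_BINARY = "tdp_binary"       # torsades-de-pointes risk yes/no
    QTC_BINARY = "qtc_binary"       # QTc prolongation yes/no
    APD_TERNARY = "apd_ternary"     # APD prolong / no effect / shorten


LABELS: dict[Endpoint, tuple[str, ...]] = {
    Endpoint.TDP_BINARY: ("risk", "no-risk"),
    Endpoint.QTC_BINARY: (_cls.PROLONG, _cls.NONE),
    Endpoint.APD_TERNARY: (_cls.PROLONG, _cls.NONE, _cls.SHORTEN),
}

# For binary endpoints, which label counts as the positive class.
_POSITIVE: dict[Endpoint, str] = {
    Endpoint.TDP_BINARY: "risk",
    Endpoint.QTC_BINARY: _cls.PROLONG,
}


def positive_label(endpoint: Endpoint) -> str:
    """The positive-class label of a binary endpoint."""
    if endpoint is Endpoint.APD_TERNARY:
        raise ValueError("ternary endpoint has no single positive label")
    return _POSITIVE[endpoint]


@dataclass(frozen=True)
class CompoundRecord:
    """A named compound: test concentration, channel activities, endpoint label."""

    compound_id: str
    concentration: float
    activities: tuple[ChannelActivity, ...]
    label: str

    def __post_init__(self) -> None:
        if not self.concentration > 0:
            raise ValueError(
                f"concentration must be > 0, got {self.concentration!r}"
            )
        channels = [a.channel for a in self.activities]
        if len(channels) != len(set(channels)):
            raise ValueError(
                f"compound {self.compound_id!r} has more than one activity "
                f"for a channel"
            )

    def activity_for(self, channel: Channel) -> ChannelActivity | None:
        for a in self.activities:
            if a.channel is channel:
                return a
        return None


@dataclass(frozen=True)
class Dataset:
    name: str
    endpoint: Endpoint
    species: str
    records: tuple[CompoundRecord, ...]

    def __post_init__(self) -> None:
        if len(self.records) == 0:
            raise ValueError("dataset must contain at least one record")
        ids = [r.compound_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("compound ids must be unique within a dataset")
        legal = set(LABELS[self.endpoint])
        bad = sorted({r.label for r in self.records} - legal)
        if bad:
            raise ValueError(
                f"labels {bad} are not legal for endpoint {self.endpoint.value}"
            )

    def labels(self) -> list[str]:
        return [r.label for r in self.records]


_UNIT_FACTORS = {"nM": 1e-3, "uM": 1.0, "µM": 1.0, "mM": 1e3}

_CHANNEL_ORDER = (Channel.IKR, Channel.ICAL, Channel.INA)


def _columns() -> list[str]:
    cols = ["compound_id", "concentration_uM", "label"]
    for ch in _CHANNEL_ORDER:
        cols += [
            f"{ch.value}_mode",
            f"{ch.value}_potency_uM",
            f"{ch.value}_n",
            f"{ch.value}_emax",
        ]
    return cols


@dataclass(frozen=True)
class SchemaConfig:
    """Unit declarations for a source file (converted to µM on load)."""

    concentration_unit: str = "uM"
    potency_unit: str = "uM"
    # per-channel overrides of potency_unit, keyed by channel name ("IKr", ...)
    potency_units: Mapping[str, str] = field(default_factory=dict)

    def factor(self, unit: str) -> float:
        try:
            return _UNIT_FACTORS[unit]
        except KeyError:
            raise ValueError(
                f"unknown concentration unit {unit!r}; expected one of "
                f"{sorted(set(_UNIT_FACTORS) - {'µM'})}"
            ) from None


class DatasetLoadError(ValueError):
    """Structured load failure listing every offending cell.

    ``errors`` is a list of (row, column, message) with 1-based data-row
    numbers (header row excluded).
    """

    def __init__(self, errors: Sequence[tuple[int | None, str | None, str]]):
        self.errors = list(errors)
        lines = []
        for row, col, msg in self.errors:
            where = []
            if row is not None:
                where.append(f"row {row}")
            if col is not None:
                where.append(f"column {col!r}")
            prefix = ", ".join(where)
            lines.append(f"{prefix}: {msg}" if prefix else msg)
        super().__init__("dataset load failed:\n  " + "\n  ".join(lines))


def _parse_metadata(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip().lower()] = value.strip()
    return meta


def read_dataset(path: str | Path, schema: SchemaConfig | None = None) -> Dataset:
    """Load a dataset, validating every cell; all rejections are reported.

    Raises :class:`DatasetLoadError` listing each offending (row, column)
    rather than failing on the first problem; rows are never silently
    dropped or coerced.
    """
    path = Path(path)
    schema = schema or SchemaConfig()
    meta = _parse_metadata(path)
    errors: list[tuple[int | None, str | None, str]] = []

    endpoint: Endpoint | None = None
    raw_endpoint = meta.get("endpoint")
    if raw_endpoint is None:
        errors.append((None, None, "missing '# endpoint = ...' metadata line"))
    else:
        try:
            endpoint = Endpoint(raw_endpoint.lower())
        except ValueError:
            errors.append(
                (None, None, f"unknown endpoint {raw_endpoint!r}; expected one of "
                             f"{[e.value for e in Endpoint]}")
            )

    frame = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    missing_cols = [c for c in _columns() if c not in frame.columns]
    if missing_cols:
        errors.append((None, None, f"missing columns: {missing_cols}"))
        raise DatasetLoadError(errors)

    conc_factor = schema.factor(schema.concentration_unit)
    legal_labels = set(LABELS[endpoint]) if endpoint is not None else None

    records: list[CompoundRecord] = []
    seen_ids: dict[str, int] = {}
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        row_map = dict(zip(frame.columns, row))
        row_errors: list[tuple[int | None, str | None, str]] = []

        cid = row_map["compound_id"].strip()
        if not cid:
            row_errors.append((i, "compound_id", "empty compound id"))
        elif cid in seen_ids:
            row_errors.append(
                (i, "compound_id",
                 f"duplicate id {cid!r} (first seen at row {seen_ids[cid]})")
            )
        else:
            seen_ids[cid] = i

        concentration = math.nan
        raw = row_map["concentration_uM"].strip()
        try:
            concentration = float(raw) * conc_factor
            if not concentration > 0:
                row_errors.append((i, "concentration_uM", f"must be > 0, got {raw!r}"))
        except ValueError:
            row_errors.append((i, "concentration_uM", f"not a number: {raw!r}"))

        label = row_map["label"].strip().lower()
        if legal_labels is not None and label not in legal_labels:
            row_errors.append(
                (i, "label", f"unknown label {row_map['label']!r}; "
                             f"expected one of {sorted(legal_labels)}")
            )

        activities: list[ChannelActivity] = []
        for ch in _CHANNEL_ORDER:
            mode_raw = row_map[f"{ch.value}_mode"].strip().lower()
            pot_raw = row_map[f"{ch.value}_potency_uM"].strip()
            n_raw = row_map[f"{ch.value}_n"].strip()
            emax_raw = row_map[f"{ch.value}_emax"].strip()
            if not mode_raw and not pot_raw:
                continue  # channel not measured
            if pot_raw.startswith(">"):
                # censored: no effect up to the top test concentration
                logger.info(
                    "row %d: censored potency %r for %s treated as no effect",
                    i, pot_raw, ch.value,
                )
                continue
            col_pot = f"{ch.value}_potency_uM"
            if mode_raw not in ("inhibitor", "agonist"):
                row_errors.append(
                    (i, f"{ch.value}_mode",
                     f"unknown mode {row_map[f'{ch.value}_mode']!r}")
                )
                continue
            mode = Mode(mode_raw)
            pot_factor = schema.factor(
                schema.potency_units.get(ch.value, schema.potency_unit)
            )
            try:
                potency = float(pot_raw) * pot_factor
            except ValueError:
                row_errors.append((i, col_pot, f"not a number: {pot_raw!r}"))
                continue
            if not potency > 0:
                row_errors.append((i, col_pot, f"must be > 0, got {pot_raw!r}"))
                continue
            hill_n = 1.0  # default when not reported
            if n_raw:
                try:
                    hill_n = float(n_raw)
                except ValueError:
                    row_errors.append((i, f"{ch.value}_n", f"not a number: {n_raw!r}"))
                    continue
                if not hill_n > 0:
                    row_errors.append((i, f"{ch.value}_n", f"must be > 0, got {n_raw!r}"))
                    continue
            emax: float | None = None
            if mode is Mode.AGONIST:
                if not emax_raw:
                    row_errors.append(
                        (i, f"{ch.value}_emax", "emax required for agonist")
                    )
                    continue
                try:
                    emax = float(emax_raw)
                except ValueError:
                    row_errors.append(
                        (i, f"{ch.value}_emax", f"not a number: {emax_raw!r}")
                    )
                    continue
                if emax < 0:
                    row_errors.append(
                        (i, f"{ch.value}_emax", f"must be >= 0, got {emax_raw!r}")
                    )
                    continue
            activities.append(
                ChannelActivity(channel=ch, mode=mode, potency=potency,
                                hill_n=hill_n, emax=emax)
            )

        if row_errors:
            errors.extend(row_errors)
        elif not errors:
            records.append(
                CompoundRecord(
                    compound_id=cid,
                    concentration=concentration,
                    activities=tuple(activities),
                    label=label,
                )
            )

    if errors:
        raise DatasetLoadError(errors)
    assert endpoint is not None
    return Dataset(
        name=meta.get("name", path.stem),
        endpoint=endpoint,
        species=meta.get("species", "unknown"),
        records=tuple(records),
    )


def _fmt(value: float | None) -> str:
    return "" if value is None else repr(float(value))


def write_dataset(dataset: Dataset, path: str | Path) -> Path:
    """Write ``dataset`` in the dialect :func:`read_dataset` accepts.

    Numeric values are written at full precision (``repr``) so a
    write/read round trip is value-identical.
    """
    path = Path(path)
    lines = [
        f"# name = {dataset.name}",
        f"# endpoint = {dataset.endpoint.value}",
        f"# species = {dataset.species}",
        ",".join(_columns()),
    ]
    for rec in dataset.records:
        cells = [rec.compound_id, _fmt(rec.concentration), rec.label]
        for ch in _CHANNEL_ORDER:
            act = rec.activity_for(ch)
            if act is None:
                cells += ["", "", "", ""]
            else:
                cells += [
                    act.mode.value,
                    _fmt(act.potency),
                    _fmt(act.hill_n),
                    _fmt(act.emax),
                ]
        lines.append(",".join(cells))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_report(
    roc_results: Sequence["ROCResult"] | None,
    cv_result: "CVResult | None",
    out_dir: str | Path,
    config_echo: Mapping[str, object] | None = None,
) -> list[Path]:
    """Write a machine-readable run report.

    Produces ``summary.csv`` (one row per question/metric, with the run
    configuration echoed as ``#`` lines for reproducibility) and one
    ``roc_<question>.csv`` point table per ROC question.  Output is
    deterministic: identical inputs yield byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    echo_lines = []
    for key in sorted(config_echo or {}):
        echo_lines.append(f"# {key} = {config_echo[key]}")

    summary_rows: list[tuple[str, str, str, str]] = []
    if roc_results:
        for res in roc_results:
            summary_rows.append(("roc", res.question_id, "auc", repr(res.auc)))
            summary_rows.append(
                ("roc", res.question_id, "n_positive", str(res.n_positive))
            )
            summary_rows.append(
                ("roc", res.question_id, "n_negative", str(res.n_negative))
            )
            roc_path = out_dir / f"roc_{res.question_id}.csv"
            lines = echo_lines + ["fpr,tpr"]
            lines += [f"{repr(f)},{repr(t)}" for f, t in res.points]
            roc_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
            written.append(roc_path)
    if cv_result is not None:
        for direction, m in sorted(cv_result.directions.items()):
            summary_rows.append(("cv", direction, "sensitivity", repr(m.sensitivity)))
            summary_rows.append(("cv", direction, "specificity", repr(m.specificity)))
            summary_rows.append(
                ("cv", direction, "balanced_accuracy", repr(m.balanced_accuracy))
            )
        summary_rows.append(("cv", "overall", "sensitivity", repr(cv_result.sensitivity)))
        summary_rows.append(("cv", "overall", "specificity", repr(cv_result.specificity)))
        summary_rows.append(
            ("cv", "overall", "balanced_accuracy", repr(cv_result.balanced_accuracy))
        )
        summary_rows.append(("cv", "overall", "n_folds", str(len(cv_result.per_fold))))
        summary_rows.append(("cv", "overall", "n_excluded", str(cv_result.n_excluded)))

        fold_path = out_dir / "cv_folds.csv"
        lines = echo_lines + [
            "compound_id,true_label,predicted_label,a0,a1,a2,t_low,t_high"
        ]
        for fold in cv_result.per_fold:
            if fold.params is None or fold.rule is None:
                lines.append(f"{fold.compound_id},{fold.true_label},,,,,,")
                continue
            t_low = "" if fold.rule.t_low is None else repr(fold.rule.t_low)
            lines.append(
                f"{fold.compound_id},{fold.true_label},{fold.predicted_label},"
                f"{repr(fold.params.a0)},{repr(fold.params.a1)},{repr(fold.params.a2)},"
                f"{t_low},{repr(fold.rule.t_high)}"
            )
        fold_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        written.append(fold_path)

    summary_path = out_dir / "summary.csv"
    lines = echo_lines + ["section,id,metric,value"]
    lines += [",".join(row) for row in summary_rows]
    summary_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    written.insert(0, summary_path)
    return written
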