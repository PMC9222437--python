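"""TSV table I/O with per-schema validation, and JSON report writing.

All tabular data is UTF-8, tab-delimited, '.' decimal — one dialect, no
sniffing.  Each schema names its required columns and converters; row-level
problems are collected and reported with 1-based file line numbers.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Subject
from .errors import ValidationError
from .lens_trial import EyeTrajectory
from .splice import SpliceMeasurement

__all__ = [
    "SCHEMAS",
    "read_table",
    "write_report",
    "load_table1_fixture",
    "subjects_from_frame",
    "measurements_from_frame",
    "trajectories_from_frame",
    "subjects_to_frame",
]


def _to_bool(v: str) -> bool:
    s = str(v).strip().lower()
    if s in ("1", "true", "t", "yes", "y"):
        return True
    if s in ("0", "false", "f", "no", "n"):
        return False
    raise ValueError(f"not a boolean: {v!r}")


#: schema name -> {column: (converter, required)}
SCHEMAS: dict[str, dict[str, tuple[Any, bool]]] = {
    "subjects": {
        "subject_id": (str, True),
        "sex": (str, False),
        "european": (_to_bool, False),
        "cv_normal": (_to_bool, False),
        "surgery": (_to_bool, False),
        "single_opn1lw": (_to_bool, False),
        "opn1lw_hap": (str, True),
        "opn1mw_haps": (str, False),
        "al_mm": (float, False),
        "cc_d": (float, False),
        "calculated_ser": (float, False),
        "percent_l": (float, False),
    },
    "assay": {
        "haplotype": (str, True),
        "replicate": (int, True),
        "auc_a": (float, True),
        "auc_t": (float, True),
    },
    "trial": {
        "subject_id": (str, True),
        "eye": (str, True),
        "arm": (str, True),
        "period": (int, True),
        "day": (int, True),
        "al_mm": (float, True),
    },
    "biometry": {
        "subject_id": (str, True),
        "eye": (str, True),
        "al_mm": (float, True),
        "cc_d": (float, True),
        "observed_ser_d": (float, False),
    },
    "haplotype_summary": {
        "haplotype": (str, True),
        "amino_acids": (str, False),
        "n": (int, True),
        "median_ser_os": (float, True),
        "mean_ser_os": (float, True),
        "pct_exon3_skipping": (float, False),
        "split_halves_rank": (float, False),
    },
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a TSV and validate it against a named schema.

    Missing required columns raise immediately; unconvertible cells are
    collected and reported together with their file line numbers.  An empty
    table (header only) is returned with a warning.
    """
    if schema not in SCHEMAS:
        raise ValidationError(
            f"unknown schema {schema!r} (have: {sorted(SCHEMAS)})"
        )
    spec = SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c, (_, req) in spec.items() if req and c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s) {missing} for schema "
            f"{schema!r}"
        )
    if df.empty:
        warnings.warn(f"{path}: table is empty", stacklevel=2)
        return df
    errors: list[str] = []
    out: dict[str, list] = {}
    for col in df.columns:
        conv = spec.get(col, (str, False))[0]
        values = []
        for i, raw in enumerate(df[col]):
            # +2: header line plus 1-based counting
            if raw == "" and not spec.get(col, (str, False))[1]:
                values.append(None)
                continue
            try:
                values.append(conv(raw))
            except (ValueError, TypeError):
                errors.append(f"line {i + 2}, column {col!r}: {raw!r}")
                values.append(None)
        out[col] = values
    if errors:
        raise ValidationError(
            f"{path}: {len(errors)} unparseable cell(s): "
            + "; ".join(errors[:10])
        )
    return pd.DataFrame(out)


def load_table1_fixture() -> pd.DataFrame:
    """The bundled 11-haplotype cohort summary table.

    ``haplotype`` holds panel-valid strings; ``printed_haplotype`` preserves
    the source spelling (one row differs — see the haplotypes module notes).
    """
    with resources.as_file(
        resources.files("opsinhap").joinpath("data/table1_fixture.tsv")
    ) as p:
        return read_table(p, "haplotype_summary")


def subjects_from_frame(df: pd.DataFrame) -> list[Subject]:
    """Build Subject records from a "subjects"-schema frame."""
    subjects = []
    for _, row in df.iterrows():
        mw = row.get("opn1mw_haps") or ""
        subjects.append(
            Subject(
                subject_id=row["subject_id"],
                opn1lw_haplotype=row["opn1lw_hap"],
                calculated_ser=row.get("calculated_ser"),
                sex=row.get("sex") or "M",
                ancestry_european=_default(row.get("european"), True),
                color_vision_normal=_default(row.get("cv_normal"), True),
                prior_surgery_or_injury=_default(row.get("surgery"), False),
                single_opn1lw=_default(row.get("single_opn1lw"), True),
                opn1mw_amino_haplotypes=tuple(
                    a for a in mw.split(",") if a
                ),
                al_mm=row.get("al_mm"),
                cc_d=row.get("cc_d"),
                percent_l=row.get("percent_l"),
            )
        )
    return subjects


def _default(v, fallback):
    return fallback if v is None else v


def subjects_to_frame(subjects: list[Subject]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "sex": [s.sex for s in subjects],
            "european": [s.ancestry_european for s in subjects],
            "cv_normal": [s.color_vision_normal for s in subjects],
            "surgery": [s.prior_surgery_or_injury for s in subjects],
            "single_opn1lw": [s.single_opn1lw for s in subjects],
            "opn1lw_hap": [s.opn1lw_haplotype for s in subjects],
            "opn1mw_haps": [
                ",".join(s.opn1mw_amino_haplotypes) for s in subjects
            ],
            "al_mm": [s.al_mm for s in subjects],
            "cc_d": [s.cc_d for s in subjects],
            "calculated_ser": [s.calculated_ser for s in subjects],
            "percent_l": [s.percent_l for s in subjects],
        }
    )


def measurements_from_frame(df: pd.DataFrame) -> list[SpliceMeasurement]:
    return [
        SpliceMeasurement(
            haplotype=row["haplotype"],
            replicate_id=int(row["replicate"]),
            auc_a=float(row["auc_a"]),
            auc_t=float(row["auc_t"]),
        )
        for _, row in df.iterrows()
    ]


def trajectories_from_frame(df: pd.DataFrame) -> list[EyeTrajectory]:
    """Assemble per-eye trajectories from long-format trial rows."""
    out = []
    keys = ["subject_id", "eye", "arm", "period"]
    for key, grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("day")
        out.append(
            EyeTrajectory(
                subject_id=str(key[0]),
                eye=str(key[1]),
                arm=str(key[2]),
                period=int(key[3]),
                days=tuple(int(d) for d in grp["day"]),
                lengths=tuple(float(v) for v in grp["al_mm"]),
            )
        )
    return out


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()
        }
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(
    results: Any,
    path: str | Path,
    seed: int | None = None,
    config: Any = None,
    force: bool = False,
) -> None:
    """Write a JSON report with a config echo, seed and version string."""
    path = Path(path)
    if path.exists() and not force:
        raise ValidationError(f"{path} exists; pass force=True to overwrite")
    payload = {
        "version": __version__,
        "seed": seed,
        "config": _jsonable(config),
        "results": _jsonable(results),
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
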