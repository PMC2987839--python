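"""Readers and writers for the tab-separated and YAML file dialects.

All tabular files are UTF-8 TSV with a header row and decimal points.
Confidence limits are always two numeric columns, never a dash-joined
token.  Validation errors name the file and the offending line.

Dialects
--------
cultures.tsv
    strain, locus, culture_id, mutant_count, n_final_cells
spectra.tsv
    category, <label1>, <label2>, ...   (one column per spectrum)
lanes.tsv
    lane_id, direction, position, intensity, is_runoff
assay.yaml
    enzyme, N, MF, expression_prob (optional), background (optional),
    classes: {name: {Ni: int, D: int}}
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .fidelity import LacZAssay, MutationClass
from .fluctuation import CultureSet
from .processivity import LaneProfile, TerminationProfile
from .spectra import MutationSpectrum

__all__ = [
    "ValidationError",
    "read_cultures",
    "write_cultures",
    "read_spectra",
    "write_spectra",
    "read_lanes",
    "write_lanes",
    "read_assay",
    "write_assay",
    "write_report",
]


class ValidationError(ValueError):
    """Malformed or invalid input file content."""


def _line_of(df_index: int) -> int:
    # +2: one for the header row, one for 1-based line numbers
    return df_index + 2


def _read_tsv(path: "str | Path", required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str).dropna(how="all")
    except Exception as exc:  # noqa: BLE001 - rewrap with filename
        raise ValidationError(f"{path}: cannot parse TSV: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return df


def _numeric(df: pd.DataFrame, col: str, path: Path, kind=float) -> pd.Series:
    def conv(item: tuple[int, str]):
        idx, val = item
        try:
            return kind(val)
        except (TypeError, ValueError):
            raise ValidationError(
                f"{path}:{_line_of(idx)}: column {col!r}: not a number: {val!r}"
            ) from None

    return pd.Series(
        [conv(t) for t in df[col].items()], index=df.index, dtype="float64"
    )


def read_cultures(path: "str | Path") -> list[CultureSet]:
    """Parse a cultures TSV into one CultureSet per (strain, locus)."""
    path = Path(path)
    df = _read_tsv(path, ["strain", "locus", "mutant_count", "n_final_cells"])
    df["_count"] = _numeric(df, "mutant_count", path)
    df["_nt"] = _numeric(df, "n_final_cells", path)
    for idx, c in df["_count"].items():
        if c < 0 or c != int(c):
            raise ValidationError(
                f"{path}:{_line_of(idx)}: mutant_count must be a non-negative integer"
            )
    out = []
    for (strain, locus), grp in df.groupby(["strain", "locus"], sort=False):
        nts = grp["_nt"].unique()
        if len(nts) != 1:
            raise ValidationError(
                f"{path}: {strain}/{locus}: n_final_cells differs across cultures"
            )
        try:
            out.append(
                CultureSet(
                    strain_label=str(strain),
                    locus_label=str(locus),
                    mutant_counts=tuple(int(c) for c in grp["_count"]),
                    n_final_cells=float(nts[0]),
                )
            )
        except ValueError as exc:
            raise ValidationError(f"{path}: {strain}/{locus}: {exc}") from exc
    return out


def write_cultures(cultures: Iterable[CultureSet], path: "str | Path") -> None:
    rows = []
    for cs in cultures:
        for i, c in enumerate(cs.mutant_counts, start=1):
            rows.append(
                {
                    "strain": cs.strain_label,
                    "locus": cs.locus_label,
                    "culture_id": i,
                    "mutant_count": c,
                    "n_final_cells": f"{cs.n_final_cells:g}",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_spectra(path: "str | Path") -> list[MutationSpectrum]:
    """Parse a spectra TSV (category column + one count column per label)."""
    path = Path(path)
    df = _read_tsv(path, ["category"])
    labels = [c for c in df.columns if c != "category"]
    if not labels:
        raise ValidationError(f"{path}: no spectrum columns besides 'category'")
    cats = tuple(df["category"])
    out = []
    for label in labels:
        counts = []
        for idx, val in df[label].items():
            try:
                c = int(val)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path}:{_line_of(idx)}: column {label!r}: not an integer: {val!r}"
                ) from None
            if c < 0:
                raise ValidationError(
                    f"{path}:{_line_of(idx)}: column {label!r}: negative count"
                )
            counts.append(c)
        out.append(
            MutationSpectrum(label=label, categories=cats, counts=tuple(counts))
        )
    return out


def write_spectra(spectra: Iterable[MutationSpectrum], path: "str | Path") -> None:
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra to write")
    cats = spectra[0].categories
    for s in spectra:
        if s.categories != cats:
            raise ValueError("all spectra must share one category list")
    df = pd.DataFrame({"category": cats})
    for s in spectra:
        df[s.label] = s.counts
    df.to_csv(path, sep="\t", index=False)


def read_lanes(path: "str | Path") -> dict[str, LaneProfile]:
    """Parse a lanes TSV into LaneProfile objects keyed by lane_id."""
    path = Path(path)
    df = _read_tsv(path, ["lane_id", "direction", "position", "intensity"])
    df["_pos"] = _numeric(df, "position", path)
    df["_int"] = _numeric(df, "intensity", path)
    for idx, v in df["_int"].items():
        if v < 0:
            raise ValidationError(
                f"{path}:{_line_of(idx)}: negative intensity"
            )
    if "is_runoff" not in df.columns:
        df["is_runoff"] = "0"
    out: dict[str, LaneProfile] = {}
    for lane_id, grp in df.groupby("lane_id", sort=False):
        directions = grp["direction"].unique()
        if len(directions) != 1:
            raise ValidationError(f"{path}: lane {lane_id}: mixed directions")
        runoff = None
        intensities: dict[int, float] = {}
        for idx, row in grp.iterrows():
            pos = int(row["_pos"])
            if pos in intensities:
                raise ValidationError(
                    f"{path}:{_line_of(idx)}: duplicate position {pos} in lane {lane_id}"
                )
            intensities[pos] = float(row["_int"])
            if str(row["is_runoff"]).strip().lower() in ("1", "true", "yes"):
                if runoff is not None:
                    raise ValidationError(
                        f"{path}: lane {lane_id}: more than one runoff band"
                    )
                runoff = pos
        try:
            out[str(lane_id)] = LaneProfile(
                direction=str(directions[0]),
                intensities=intensities,
                runoff_position=runoff,
            )
        except ValueError as exc:
            raise ValidationError(f"{path}: lane {lane_id}: {exc}") from exc
    return out


def write_lanes(lanes: Mapping[str, LaneProfile], path: "str | Path") -> None:
    rows = []
    for lane_id, lane in lanes.items():
        for pos in sorted(lane.intensities):
            rows.append(
                {
                    "lane_id": lane_id,
                    "direction": lane.direction,
                    "position": pos,
                    "intensity": repr(lane.intensities[pos]),
                    "is_runoff": int(pos == lane.runoff_position),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_assay(path: "str | Path") -> LacZAssay:
    """Parse a lacZ assay summary from YAML."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: expected a YAML mapping")
    try:
        classes = {
            str(name): MutationClass(int(spec["Ni"]), int(spec["D"]))
            for name, spec in (raw.get("classes") or {}).items()
        }
        return LacZAssay(
            enzyme_label=str(raw["enzyme"]),
            n_mutants_sequenced=int(raw["N"]),
            mutant_frequency=float(raw["MF"]),
            classes=classes,
            background_frequency=(
                float(raw["background"]) if raw.get("background") is not None else None
            ),
            expression_prob=float(raw.get("expression_prob", 0.6)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: invalid assay file: {exc}") from exc


def write_assay(assay: LacZAssay, path: "str | Path") -> None:
    doc = {
        "enzyme": assay.enzyme_label,
        "N": assay.n_mutants_sequenced,
        "MF": assay.mutant_frequency,
        "expression_prob": assay.expression_prob,
        "classes": {
            name: {"Ni": mc.ni, "D": mc.detectable_sites}
            for name, mc in assay.classes.items()
        },
    }
    if assay.background_frequency is not None:
        doc["background"] = assay.background_frequency
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_report(
    rows: "pd.DataFrame | list[dict]", path: "str | Path", float_decimals: int = 6
) -> None:
    """Write a results table as TSV with a fixed float format."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, float_format=f"%.{float_decimals}g")
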