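"""Treatment-response classification of monotonically expressed genes.

A monotonically expressed gene (MEG) found in a response group is joined
with its cross-sectional differential-expression direction (case versus
control). A discordant pair — the gene drifts back toward control levels
over treatment, e.g. an underexpressed gene increasing monotonically — is a
"good response" gene; a concordant pair — the gene drifts further away — is
a "bad response" gene.

This module also loads the packaged worked-example fixtures: the patient
table with first-relapse categories (used to split responders from
nonresponders) and the published MEG direction table.
"""

from __future__ import annotations

import re
from importlib import resources

import pandas as pd

from .errors import InputError

GOOD = "good"
BAD = "bad"

_UP_TOKENS = {"up", "↑", "increasing", "mie", "over", "overexpressed"}
_DOWN_TOKENS = {"down", "↓", "decreasing", "mde", "under", "underexpressed"}


def _normalize_direction(token: str) -> str:
    key = str(token).strip().lower()
    if key in _UP_TOKENS:
        return "up"
    if key in _DOWN_TOKENS:
        return "down"
    raise InputError(f"unknown direction token {token!r}")


def classify_response(meg_direction: str, deg_direction: str) -> str:
    """Good iff the monotone and differential directions are opposite."""
    meg = _normalize_direction(meg_direction)
    deg = _normalize_direction(deg_direction)
    return GOOD if meg != deg else BAD


def classify_all(megs: pd.DataFrame, degs: pd.DataFrame, group: str) -> pd.DataFrame:
    """Classify every MEG of one group against the DEG direction table.

    ``megs``: gene-indexed with a ``direction`` column (monotone direction).
    ``degs``: gene-indexed with a ``direction`` column (DE direction).
    Output is one record per MEG with columns ``gene, group, meg_direction,
    deg_direction, classification``, sorted good-before-bad then by symbol.
    """
    missing = [g for g in megs.index if g not in degs.index]
    if missing:
        raise InputError(
            f"MEGs absent from the DEG set (pipeline wiring bug): {missing[:5]}"
        )
    records = []
    for gene in megs.index:
        meg_dir = _normalize_direction(megs.loc[gene, "direction"])
        deg_dir = _normalize_direction(degs.loc[gene, "direction"])
        records.append(
            {
                "gene": gene,
                "group": group,
                "meg_direction": meg_dir,
                "deg_direction": deg_dir,
                "classification": classify_response(meg_dir, deg_dir),
            }
        )
    frame = pd.DataFrame(records, columns=["gene", "group", "meg_direction", "deg_direction", "classification"])
    order = {GOOD: 0, BAD: 1}
    return frame.sort_values(
        by=["classification", "gene"], key=lambda s: s.map(order) if s.name == "classification" else s
    ).reset_index(drop=True)


_GT = re.compile(r"^>\s*(\d+)\s*months?$")
_LT = re.compile(r"^<\s*(\d+)\s*months?$")
_RANGE = re.compile(r"^(\d+)\s*[-~–∼]\s*(\d+)\s*months?$")


def filter_patients(
    records: pd.DataFrame,
    responder_min_months: float = 60,
    nonresponder_max_months: float = 24,
) -> tuple[list, list, list]:
    """Split patients by first-relapse category.

    Responders relapsed later than ``responder_min_months`` after treatment
    start; nonresponders earlier than ``nonresponder_max_months``; patients
    in between are excluded from the analysis. ``records`` needs columns
    ``patient_id`` and ``category`` (e.g. ">60 months", "24-60 months",
    "<24 months"). Returns ``(responders, nonresponders, excluded)`` id
    lists in input order.
    """
    responders, nonresponders, excluded = [], [], []
    for _, row in records.iterrows():
        category = str(row["category"]).strip()
        pid = row["patient_id"]
        m = _GT.match(category)
        if m:
            if float(m.group(1)) >= responder_min_months:
                responders.append(pid)
            else:
                excluded.append(pid)
            continue
        m = _LT.match(category)
        if m:
            if float(m.group(1)) <= nonresponder_max_months:
                nonresponders.append(pid)
            else:
                excluded.append(pid)
            continue
        m = _RANGE.match(category)
        if m:
            lo, hi = float(m.group(1)), float(m.group(2))
            if lo >= responder_min_months:
                responders.append(pid)
            elif hi <= nonresponder_max_months:
                nonresponders.append(pid)
            else:
                excluded.append(pid)
            continue
        raise InputError(f"unknown first-relapse category {category!r}")
    return responders, nonresponders, excluded


def _fixture_path(name: str):
    return resources.files("megscreen") / "fixtures" / name


def load_patient_fixture() -> pd.DataFrame:
    """Packaged patient table (patient_id, first-relapse category)."""
    with resources.as_file(_fixture_path("table1_patients.tsv")) as path:
        return pd.read_csv(path, sep="\t", dtype={"patient_id": int, "category": str})


def load_meg_fixture() -> pd.DataFrame:
    """Packaged published MEG table (symbol, group, directions, class)."""
    with resources.as_file(_fixture_path("table2_megs.tsv")) as path:
        return pd.read_csv(path, sep="\t")
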