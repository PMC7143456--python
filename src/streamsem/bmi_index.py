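"""Benthic Macroinvertebrate Index (BMI) scoring.

The index is a saprobic-value weighted mean rescaled to 0-100:

    score = (4 - sum(s_i * h_i * q_i) / sum(h_i * q_i)) * 25

where ``s`` is a taxon's saprobic value on the 0-4 tolerance scale, ``h``
its frequency (abundance), and ``q`` its indicator weight. 100 means
excellent stream condition, 0 poor.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TaxaRecord",
    "TaxaValidationError",
    "compute_bmi",
    "bmi_per_site",
    "read_taxa_csv",
]

TAXA_COLUMNS = ("taxon", "s", "h", "q")


class TaxaValidationError(ValueError):
    """Raised for an empty or invalid taxa table."""


@dataclasses.dataclass(frozen=True)
class TaxaRecord:
    """One taxon's saprobic value ``s``, frequency ``h``, and weight ``q``."""

    taxon_id: str
    s: float
    h: float
    q: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 4.0:
            raise TaxaValidationError(
                f"taxon {self.taxon_id!r}: saprobic value s={self.s} outside [0, 4]"
            )
        if not self.h > 0.0:
            raise TaxaValidationError(f"taxon {self.taxon_id!r}: frequency h={self.h} must be > 0")
        if not self.q > 0.0:
            raise TaxaValidationError(
                f"taxon {self.taxon_id!r}: indicator weight q={self.q} must be > 0"
            )


def _as_records(taxa) -> list[TaxaRecord]:
    if isinstance(taxa, pd.DataFrame):
        missing = [c for c in ("s", "h", "q") if c not in taxa.columns]
        if missing:
            raise TaxaValidationError(f"taxa table missing columns: {missing}")
        ids = (
            taxa["taxon"].astype(str).tolist()
            if "taxon" in taxa.columns
            else [str(i) for i in taxa.index]
        )
        return [
            TaxaRecord(tid, float(s), float(h), float(q))
            for tid, s, h, q in zip(ids, taxa["s"], taxa["h"], taxa["q"])
        ]
    return [r if isinstance(r, TaxaRecord) else TaxaRecord(*r) for r in taxa]


def _merge_duplicates(records: list[TaxaRecord]) -> list[TaxaRecord]:
    # repeated field picks of one taxon are pooled by summing frequencies
    by_id: dict[str, TaxaRecord] = {}
    order: list[str] = []
    for rec in records:
        if rec.taxon_id in by_id:
            prev = by_id[rec.taxon_id]
            if prev.s != rec.s or prev.q != rec.q:
                raise TaxaValidationError(
                    f"taxon {rec.taxon_id!r}: duplicate rows with conflicting s or q"
                )
            by_id[rec.taxon_id] = dataclasses.replace(prev, h=prev.h + rec.h)
            logger.warning("duplicate taxon %r: frequencies summed", rec.taxon_id)
        else:
            by_id[rec.taxon_id] = rec
            order.append(rec.taxon_id)
    return [by_id[t] for t in order]


def compute_bmi(taxa: pd.DataFrame | Iterable[TaxaRecord]) -> float:
    """Score a taxa table; returns a float in [0, 100].

    Raises :class:`TaxaValidationError` for an empty table ("no taxa") or
    any record violating ``0 <= s <= 4``, ``h > 0``, ``q > 0``.
    """
    records = _merge_duplicates(_as_records(taxa))
    if not records:
        raise TaxaValidationError("no taxa")
    num = math.fsum(r.s * r.h * r.q for r in records)
    den = math.fsum(r.h * r.q for r in records)
    score = (4.0 - num / den) * 25.0
    return min(max(score, 0.0), 100.0)


def bmi_per_site(
    taxa_by_site: Mapping[str, pd.DataFrame | Iterable[TaxaRecord]],
) -> tuple[dict[str, float], list[str]]:
    """Score each site's taxa table.

    Returns ``(scores, missing)`` where ``missing`` lists sites whose table
    was empty (reported as absent, never as a zero score). Validation errors
    are re-raised with the site label prepended.
    """
    scores: dict[str, float] = {}
    missing: list[str] = []
    for site, taxa in taxa_by_site.items():
        try:
            records = _as_records(taxa)
            if not records:
                missing.append(site)
                continue
            scores[site] = compute_bmi(records)
        except TaxaValidationError as exc:
            raise TaxaValidationError(f"site {site!r}: {exc}") from None
    return scores, missing


def read_taxa_csv(path) -> dict[str, pd.DataFrame]:
    """Read a long-format taxa CSV (``site,taxon,s,h,q``) grouped by site."""
    df = pd.read_csv(path)
    missing = [c for c in ("site",) + TAXA_COLUMNS if c not in df.columns]
    if missing:
        raise TaxaValidationError(f"taxa CSV missing columns: {missing}")
    return {str(site): grp.drop(columns="site") for site, grp in df.groupby("site", sort=False)}
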