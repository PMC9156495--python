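"""Error-normalised fold change (ENFC) between phenotypes per compartment.

The package's ENFC is a standardized log2 fold change: with group means
m_ref, m_case (> 0), sample sds s_ref, s_case and sizes n_ref, n_case >= 2,

    ENFC = log2(m_case / m_ref) / SE
    SE   = (1 / ln 2) * sqrt( s_case^2 / (n_case * m_case^2)
                            + s_ref^2  / (n_ref  * m_ref^2 ) )

i.e. the log2 fold change divided by its delta-method standard error.
Positive values mean higher abundance in the non-reference (case) group.
Whether the original tool used log2 or natural log, and its exact error
propagation, is not published alongside it; this definition is documented
here and an alternative callable can be substituted via the pipeline
configuration.  Undefined situations (zero mean in either group, n < 2)
are flagged, never silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .dataset_io import AbundanceTable, GroupSummary, summarise_groups
from .nomenclature import TaggingPolicy, DEFAULT_POLICY, tag_species

__all__ = ["ENFCRecord", "enfc", "class_enfc", "subclass_panel"]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class ENFCRecord:
    unit: str
    compartment: str
    mean_ref: float
    sd_ref: float
    n_ref: int
    mean_case: float
    sd_case: float
    n_case: int
    enfc: float | None
    undefined_flag: bool = False
    reason: str = ""


def enfc(
    mean_ref: float,
    sd_ref: float,
    n_ref: int,
    mean_case: float,
    sd_case: float,
    n_case: int,
) -> tuple[float | None, bool, str]:
    """Error-normalised fold change of case vs reference group summaries.

    Returns ``(value, undefined_flag, reason)``.  ``value`` is ``None`` when
    undefined (zero mean or n < 2) and ``+/-inf`` when both sds are zero but
    the means differ (flagged, sign of the fold direction).
    """
    for label, val in (
        ("mean_ref", mean_ref), ("sd_ref", sd_ref),
        ("mean_case", mean_case), ("sd_case", sd_case),
    ):
        if val < 0:
            raise ValueError(f"{label} must be non-negative, got {val}")
    if n_ref < 1 or n_case < 1:
        raise ValueError("group sizes must be >= 1")
    if mean_ref == 0:
        return None, True, "zero reference mean"
    if mean_case == 0:
        return None, True, "zero case mean"
    if n_ref < 2 or n_case < 2:
        return None, True, "group size below 2"
    lfc = math.log2(mean_case / mean_ref)
    se = (1.0 / LN2) * math.sqrt(
        sd_case**2 / (n_case * mean_case**2) + sd_ref**2 / (n_ref * mean_ref**2)
    )
    if se == 0.0:
        if lfc == 0.0:
            return 0.0, False, ""
        return math.copysign(math.inf, lfc), True, "zero standard error"
    return lfc / se, False, ""


def _records_from_summary(
    summary: GroupSummary, reference: str, units: list[str] | None = None
) -> list[ENFCRecord]:
    df = summary.data
    phenos = sorted(df["phenotype"].unique()) if not df.empty else []
    case_labels = [p for p in phenos if p != reference]
    if df.empty:
        return []
    if reference not in phenos or len(case_labels) != 1:
        raise ValueError(
            f"reference {reference!r} must be one of the two phenotypes {phenos}"
        )
    case = case_labels[0]
    records = []
    seen_pairs = df[["unit", "compartment"]].drop_duplicates().itertuples(index=False)
    for unit, comp in seen_pairs:
        if units is not None and unit not in units:
            continue
        ref_row = summary.lookup(unit, comp, reference)
        case_row = summary.lookup(unit, comp, case)
        if ref_row is None or case_row is None:
            continue  # group entirely absent from this compartment
        value, flag, reason = enfc(
            float(ref_row["mean"]), float(ref_row["sd"]), int(ref_row["n"]),
            float(case_row["mean"]), float(case_row["sd"]), int(case_row["n"]),
        )
        records.append(
            ENFCRecord(
                unit=unit,
                compartment=comp,
                mean_ref=float(ref_row["mean"]),
                sd_ref=float(ref_row["sd"]),
                n_ref=int(ref_row["n"]),
                mean_case=float(case_row["mean"]),
                sd_case=float(case_row["sd"]),
                n_case=int(case_row["n"]),
                enfc=value,
                undefined_flag=flag,
                reason=reason,
            )
        )
    return records


def class_enfc(tbl: AbundanceTable, reference: str) -> list[ENFCRecord]:
    """ENFC per (head-group class, compartment).

    Class values are per-sample sums over the class's species (absent
    species contributing 0), summarised and passed through :func:`enfc`.
    Rows are ordered by compartment (network order) then class.
    """
    summary = summarise_groups(tbl, level="class")
    return _records_from_summary(summary, reference)


def subclass_panel(
    tbl: AbundanceTable,
    selector: str | list[str],
    reference: str,
    policy: TaggingPolicy = DEFAULT_POLICY,
) -> list[ENFCRecord]:
    """Species-level ENFC restricted to a tag or an explicit species list.

    ``selector`` is either a tag name (``"DNL_MARKER"``, ``"PUFA"``,
    ``"OTHER"``) or a list of species names.  Rows are ordered by
    compartment then species; an empty selection is an error.
    """
    if isinstance(selector, str) and selector.upper() in {"DNL_MARKER", "PUFA", "OTHER"}:
        tag = selector.upper()
        chosen = [
            name
            for name, sp in tbl.species.items()
            if tag in tag_species(sp, policy).tags
        ]
    else:
        names = [selector] if isinstance(selector, str) else list(selector)
        from .nomenclature import parse_lipid_name

        wanted = {parse_lipid_name(n).name for n in names}
        chosen = [name for name in tbl.species if name in wanted]
    if not chosen:
        raise ValueError(f"selector {selector!r} matches no species in the table")
    chosen.sort(key=lambda name: tbl.species[name].sort_key())
    summary = summarise_groups(tbl, level="species")
    return _records_from_summary(summary, reference, units=chosen)


def records_to_frame(records: list[ENFCRecord]) -> pd.DataFrame:
    """Flatten ENFC records into a result table."""
    return pd.DataFrame(
        [
            {
                "unit": r.unit,
                "compartment": r.compartment,
                "mean_ref": r.mean_ref,
                "sd_ref": r.sd_ref,
                "n_ref": r.n_ref,
                "mean_case": r.mean_case,
                "sd_case": r.sd_case,
                "n_case": r.n_case,
                "enfc": r.enfc if r.enfc is not None else "",
                "undefined": r.undefined_flag,
                "reason": r.reason,
            }
            for r in records
        ],
        columns=[
            "unit", "compartment", "mean_ref", "sd_ref", "n_ref",
            "mean_case", "sd_case", "n_case", "enfc", "undefined", "reason",
        ],
    )
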