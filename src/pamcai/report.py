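"""End-to-end assembly of the trial analysis and report rendering.

``run_pipeline`` takes a validated cohort and produces the four
publication-style tables (baseline characteristics; primary/secondary
outcome comparisons with barrier-resolution category rows; per-participant
barrier detail; resource use, costs and the cost-utility analysis) plus
CONSORT-style flow counts and the headline ordinal association between
barrier resolution and adherence change.

Analysis follows intention to treat: participants are analysed in their
randomised arm, and a participant missing follow-up contributes available
(baseline) data only; each table carries its effective n.  All statistics
are computed by the dedicated modules (no re-implementation here), so the
report is bit-identical on re-runs of the same cohort and options.
"""

from __future__ import annotations

import csv as _csv
import io as _io
import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional

import numpy as np

from . import adherence as adh
from . import econ, stats
from .types import Arm, ParticipantRecord, PriceTable

__all__ = ["PipelineOptions", "TrialReport", "run_pipeline", "render_report"]

ARMS = (Arm.usual_care, Arm.intervention)


@dataclass(frozen=True)
class PipelineOptions:
    wtp: float = econ.DEFAULT_WTP
    adherence_mode: str = "conservative"
    extrapolation: str = "locf"
    #: optional recruitment funnel counts; default collapses to the cohort size
    screened: Optional[int] = None
    contacted: Optional[int] = None
    consented: Optional[int] = None


@dataclass
class TrialReport:
    baseline_table: dict
    outcomes_table: dict
    barrier_table: dict
    econ_table: dict
    flow_counts: dict
    association: dict
    effect_size: dict
    notes: list

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrialReport":
        return cls(**d)


def _r2(x) -> Optional[float]:
    return None if x is None else round(float(x), 2)


def _mean_sd(values: list[float]) -> tuple[Optional[float], Optional[float]]:
    if not values:
        return None, None
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
    return float(np.mean(arr)), sd


def _derive(rec: ParticipantRecord, mode: str) -> dict:
    """Per-participant derived quantities used across tables."""
    out: dict = {"id": rec.participant_id, "arm": rec.arm.value}
    for tp_name in ("baseline", "followup"):
        tp = getattr(rec, tp_name)
        if tp is not None and tp.wear_report is not None:
            pct = adh.adherence_percentage(tp.wear_report, mode=mode)
            out[f"{tp_name}_pct"] = pct
            out[f"{tp_name}_mq10"] = adh.modified_q10(pct)
        if tp is not None:
            out[f"{tp_name}_q10"] = tp.vcss_q10
            out[f"{tp_name}_vcss"] = tp.vcss_total
            out[f"{tp_name}_civiq"] = tp.civiq14_gis
            out[f"{tp_name}_utility"] = tp.eq5d_utility
            out[f"{tp_name}_vas"] = tp.eq5d_vas
    for name in ("pct", "mq10", "q10", "vcss", "civiq", "utility", "vas"):
        b, f = out.get(f"baseline_{name}"), out.get(f"followup_{name}")
        out[f"change_{name}"] = (f - b) if (b is not None and f is not None) else None
    if rec.barrier_outcomes:
        out["mean_resolution"] = adh.mean_barrier_resolution(rec.barrier_outcomes)
    out["n_barriers"] = len(rec.barrier_assessment.responses)
    return out


_BASELINE_MEASURES = [
    ("age", "Age, years"),
    ("bmi", "BMI, kg/m^2"),
    ("baseline_pct", "Adherence percentage score"),
    ("baseline_mq10", "Modified VCSS Q10"),
    ("baseline_q10", "VCSS Q10 (clinician-assigned)"),
    ("baseline_vcss", "VCSS total"),
    ("baseline_civiq", "CIVIQ-14 GIS"),
    ("baseline_utility", "EQ-5D-5L utility"),
    ("baseline_vas", "EQ-5D-5L VAS"),
]

#: (derived-value key, label, test) for the outcomes table; the primary
#: ordinal scales use Mann-Whitney, secondaries the baseline-adjusted OLS
_OUTCOME_ROWS = [
    ("q10", "VCSS Q10 change", "mann_whitney"),
    ("mq10", "Modified VCSS Q10 change", "mann_whitney"),
    ("pct", "Average daily hours in stockings (%) change", "ancova"),
    ("vcss", "VCSS total change", "ancova"),
    ("civiq", "CIVIQ-14 GIS change", "ancova"),
    ("utility", "EQ-5D-5L utility change", "ancova"),
    ("vas", "EQ-5D-5L VAS change", "ancova"),
]


def run_pipeline(
    cohort: Iterable[ParticipantRecord],
    prices: Optional[PriceTable] = None,
    options: PipelineOptions = PipelineOptions(),
) -> TrialReport:
    cohort = list(cohort)
    notes: list[str] = []
    by_arm = {a: [r for r in cohort if r.arm is a] for a in ARMS}
    if any(not members for members in by_arm.values()):
        raise ValueError("cohort must contain participants in both arms")

    derived = {r.participant_id: _derive(r, options.adherence_mode) for r in cohort}

    # ---- baseline table ---------------------------------------------------
    baseline_rows = []
    for key, label in _BASELINE_MEASURES:
        row = {"measure": label}
        for arm in ARMS:
            vals = [derived[r.participant_id][key] for r in by_arm[arm]
                    if derived[r.participant_id].get(key) is not None]
            m, s = _mean_sd(vals)
            row[f"{arm.value}_mean"] = _r2(m)
            row[f"{arm.value}_sd"] = _r2(s)
            row[f"{arm.value}_n"] = len(vals)
        baseline_rows.append(row)
    p_female = {
        arm.value: _r2(100 * np.mean([r.gender.value == "female" for r in by_arm[arm]]))
        for arm in ARMS
    }

    # ---- outcomes table ---------------------------------------------------
    outcome_rows = []
    for key, label, test in _OUTCOME_ROWS:
        per_arm: dict[Arm, list] = {}
        for arm in ARMS:
            per_arm[arm] = [
                (derived[r.participant_id][f"change_{key}"], derived[r.participant_id].get(f"baseline_{key}"))
                for r in by_arm[arm]
                if derived[r.participant_id].get(f"change_{key}") is not None
            ]
        row = {"outcome": label, "test": test}
        means = {}
        for arm in ARMS:
            changes = [c for c, _ in per_arm[arm]]
            m, s = _mean_sd(changes)
            means[arm] = m
            row[f"{arm.value}_mean_change"] = _r2(m)
            row[f"{arm.value}_sd"] = _r2(s)
            row[f"{arm.value}_n"] = len(changes)
        if any(len(per_arm[a]) == 0 for a in ARMS):
            row.update(difference=None, p_value=None)
            outcome_rows.append(row)
            notes.append(f"{label}: at least one arm has no analysable change scores")
            continue
        row["difference"] = _r2(means[Arm.intervention] - means[Arm.usual_care])
        if test == "mann_whitney":
            res = stats.mann_whitney(
                [c for c, _ in per_arm[Arm.usual_care]], [c for c, _ in per_arm[Arm.intervention]]
            )
            row["p_value"] = round(res.p_value, 4)
            row["statistic"] = res.statistic
            row["method"] = res.method.value
        else:
            changes, arms_ind, baselines = [], [], []
            for arm in ARMS:
                for c, b in per_arm[arm]:
                    if b is None:
                        continue
                    changes.append(c)
                    arms_ind.append(1 if arm is Arm.intervention else 0)
                    baselines.append(b)
            try:
                reg = stats.adjusted_group_effect(changes, arms_ind, baselines)
                row["adjusted_difference"] = round(reg.group_effect, 4)
                row["p_value"] = round(reg.p_value, 4)
                row["method"] = "ancova"
            except ValueError as exc:
                row["p_value"] = None
                notes.append(f"{label}: baseline-adjusted regression not estimable ({exc})")
        outcome_rows.append(row)

    # barrier-resolution category rows (pooled per arm), appended as in the
    # trial's outcome table
    summaries = {
        arm: adh.summarize_resolution([r.barrier_outcomes for r in by_arm[arm]]) for arm in ARMS
    }
    resolution_rows = []
    for cat in adh.RESOLUTION_CATEGORIES:
        row = {"category": cat}
        for arm in ARMS:
            s = summaries[arm]
            row[f"{arm.value}_n"] = s.counts[cat]
            row[f"{arm.value}_pct"] = s.percentages[cat] if s.percentages_defined else None
        if all(summaries[a].percentages_defined for a in ARMS):
            row["difference_pct"] = _r2(
                summaries[Arm.intervention].percentages[cat] - summaries[Arm.usual_care].percentages[cat]
            )
        resolution_rows.append(row)

    # ---- headline ordinal association --------------------------------------
    assoc_pred, assoc_resp = [], []
    for r in cohort:
        d = derived[r.participant_id]
        if d.get("mean_resolution") is not None and d.get("change_mq10") is not None:
            assoc_pred.append(d["mean_resolution"])
            assoc_resp.append(d["change_mq10"])
    association: dict = {"n": len(assoc_pred)}
    try:
        d_val, p_val = stats.somers_d(assoc_pred, assoc_resp)
        association.update(somers_d=round(d_val, 4), p_value=round(p_val, 4))
    except ValueError as exc:
        association.update(somers_d=None, p_value=None)
        notes.append(f"Somers' D not estimable: {exc}")

    # ---- effect size on the primary outcome --------------------------------
    eff: dict = {}
    mq = {
        arm: [derived[r.participant_id]["change_mq10"] for r in by_arm[arm]
              if derived[r.participant_id].get("change_mq10") is not None]
        for arm in ARMS
    }
    if all(len(v) >= 2 for v in mq.values()):
        m1, s1 = _mean_sd(mq[Arm.usual_care])
        m2, s2 = _mean_sd(mq[Arm.intervention])
        try:
            d_eff = stats.cohens_d_pooled(m1, s1, len(mq[Arm.usual_care]), m2, s2, len(mq[Arm.intervention]))
            eff = {"cohens_d": round(d_eff, 4), "outcome": "Modified VCSS Q10 change"}
        except ZeroDivisionError:
            eff = {"cohens_d": None, "outcome": "Modified VCSS Q10 change", "note": "zero pooled SD"}

    # ---- barrier table ------------------------------------------------------
    barrier_rows = []
    for r in cohort:
        d = derived[r.participant_id]
        barrier_rows.append(
            {
                "participant_id": r.participant_id,
                "arm": r.arm.value,
                "barrier_ids": ";".join(str(b) for b in sorted(r.barrier_assessment.responses)),
                "n_barriers": d["n_barriers"],
                "pct_change": _r2(d.get("change_pct")),
                "modified_q10_change": d.get("change_mq10"),
                "mean_resolution_score": d.get("mean_resolution"),
            }
        )

    # ---- economics ----------------------------------------------------------
    prices = prices or PriceTable()
    cua = econ.cost_utility_analysis(
        cohort, prices, wtp=options.wtp, extrapolation=options.extrapolation
    )
    econ_rows = []
    for arm in ARMS:
        members = by_arm[arm]
        breakdowns = [econ.cost_participant(r.resource_use, prices) for r in members]
        totals = [b.total for b in breakdowns]
        m, s = _mean_sd(totals)
        econ_rows.append(
            {
                "arm": arm.value,
                "n": len(members),
                "mean_f2f_appointments": _r2(np.mean([r.resource_use.n_f2f_appointments for r in members])),
                "mean_phone_appointments": _r2(np.mean([r.resource_use.n_phone_appointments for r in members])),
                "mean_appointment_cost": _r2(np.mean([b.appointment_cost for b in breakdowns])),
                "mean_materials_cost": _r2(np.mean([b.materials_cost for b in breakdowns])),
                "mean_total_cost": _r2(m),
                "sd_total_cost": _r2(s),
            }
        )
    econ_table = {
        "columns": list(econ_rows[0].keys()),
        "rows": econ_rows,
        "cua": {
            "delta_cost": cua.delta_cost,
            "qaly_per_arm": cua.qaly_per_arm,
            "delta_qaly_unadjusted": cua.delta_qaly_unadjusted,
            "delta_qaly_adjusted": cua.delta_qaly_adjusted,
            "icer": cua.icer,
            "dominance": cua.dominance.value,
            "wtp_threshold": cua.wtp_threshold,
            "cost_effective": cua.cost_effective,
        },
    }
    notes.extend(cua.notes)

    # ---- flow counts --------------------------------------------------------
    randomised = {arm.value: len(by_arm[arm]) for arm in ARMS}
    analysed = {arm.value: sum(r.has_followup for r in by_arm[arm]) for arm in ARMS}
    n_rand = sum(randomised.values())
    consented = options.consented if options.consented is not None else n_rand
    contacted = options.contacted if options.contacted is not None else consented
    screened = options.screened if options.screened is not None else contacted
    if not (sum(analysed.values()) <= n_rand <= consented <= contacted <= screened):
        raise ValueError("flow counts must satisfy analysed <= randomised <= consented <= contacted <= screened")
    flow = {
        "screened": screened,
        "contacted": contacted,
        "consented": consented,
        "randomised": randomised,
        "analysed": analysed,
    }

    return TrialReport(
        baseline_table={
            "columns": list(baseline_rows[0].keys()),
            "rows": baseline_rows,
            "percent_female": p_female,
        },
        outcomes_table={
            "columns": [
                "outcome",
                "usual_care_mean_change",
                "usual_care_sd",
                "intervention_mean_change",
                "intervention_sd",
                "difference",
                "p_value",
            ],
            "rows": outcome_rows,
            "resolution_rows": resolution_rows,
            "total_barriers": {arm.value: summaries[arm].total_barriers for arm in ARMS},
        },
        barrier_table={"columns": list(barrier_rows[0].keys()), "rows": barrier_rows},
        econ_table=econ_table,
        flow_counts=flow,
        association=association,
        effect_size=eff,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# rendering

def _md_table(columns: list[str], rows: list[dict]) -> str:
    def cell(v):
        return "" if v is None else str(v)

    lines = ["| " + " | ".join(columns) + " |", "| " + " | ".join("---" for _ in columns) + " |"]
    for row in rows:
        lines.append("| " + " | ".join(cell(row.get(c)) for c in columns) + " |")
    return "\n".join(lines)


def _csv_block(columns: list[str], rows: list[dict]) -> str:
    buf = _io.StringIO()
    writer = _csv.DictWriter(buf, fieldnames=columns, extrasaction="ignore")
    writer.writeheader()
    for row in rows:
        writer.writerow({c: ("" if row.get(c) is None else row.get(c)) for c in columns})
    return buf.getvalue()


def render_report(report: TrialReport, format: str = "markdown") -> str:
    """Serialize a report deterministically as markdown, json or csv."""
    if format == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=False)
    if format == "markdown":
        parts = ["# Trial report", "", "## Baseline characteristics", ""]
        parts.append(_md_table(report.baseline_table["columns"], report.baseline_table["rows"]))
        parts += ["", f"Percent female: {report.baseline_table['percent_female']}", "", "## Outcomes", ""]
        parts.append(_md_table(report.outcomes_table["columns"], report.outcomes_table["rows"]))
        parts += ["", "### Barrier resolution (pooled)", ""]
        res_cols = list(report.outcomes_table["resolution_rows"][0].keys())
        parts.append(_md_table(res_cols, report.outcomes_table["resolution_rows"]))
        parts += [
            "",
            f"Somers' D (resolution vs adherence change): {report.association}",
            f"Effect size: {report.effect_size}",
            "",
            "## Participant barriers",
            "",
        ]
        parts.append(_md_table(report.barrier_table["columns"], report.barrier_table["rows"]))
        parts += ["", "## Costs and cost-utility", ""]
        parts.append(_md_table(report.econ_table["columns"], report.econ_table["rows"]))
        parts += ["", f"CUA: {report.econ_table['cua']}", "", f"Flow: {report.flow_counts}", ""]
        if report.notes:
            parts += ["## Notes", ""] + [f"- {n}" for n in report.notes]
        return "\n".join(parts) + "\n"
    if format == "csv":
        blocks = []
        for name, table in (
            ("baseline_table", report.baseline_table),
            ("outcomes_table", report.outcomes_table),
            ("barrier_table", report.barrier_table),
            ("econ_table", report.econ_table),
        ):
            blocks.append(f"# {name}\n" + _csv_block(table["columns"], table["rows"]))
        return "\n".join(blocks)
    raise ValueError(f"unknown format {format!r}")
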