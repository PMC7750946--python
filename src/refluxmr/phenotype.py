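"""Reflux-disease (GORD) case/control derivation from EHR code lists.

Four nested definitions are derived per individual:

primary
    case iff self-report code 1138, ICD10 K21.9 or K21.0, or OPCS4
    anti-reflux operation code G24/G25 is present; everyone else is a
    control.
sensitivity 1 (SA1)
    cases whose only evidence is self-report are excluded; controls on
    acid-suppressant medication or with an upper-GI endoscopy code (G45)
    are excluded as possible undiagnosed reflux.
sensitivity 2 (SA2)
    additionally excludes cases without the erosive-oesophagitis code
    K21.0; controls as SA1.
sensitivity 3 (SA3)
    keeps only cases with an anti-reflux operation code (G24/G25) plus at
    least one other confirming code; controls as SA1.

The case sets nest: SA3 subset of SA2 subset of SA1 subset of primary.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "CodedIndividual",
    "derive_primary",
    "derive_sensitivity",
    "derive_all",
    "tabulate_flowchart",
]

SELF_REPORT_CASE = {1138}
ICD10_CASE = {"K21.9", "K21.0"}
ICD10_EROSIVE = {"K21.0"}
OPCS4_SURGERY = {"G24", "G25"}

CASE, CONTROL, EXCLUDED = "case", "control", "excluded"


class CodedIndividual:
    """Code lists and flags for one individual (convenience record)."""

    def __init__(self, id, self_report_codes=(), icd10_codes=(),
                 opcs4_codes=(), on_acid_suppressant=False,
                 had_endoscopy_g45=False):
        self.id = id
        self.self_report_codes = {int(c) for c in self_report_codes}
        self.icd10_codes = set(icd10_codes)
        self.opcs4_codes = set(opcs4_codes)
        self.on_acid_suppressant = bool(on_acid_suppressant)
        self.had_endoscopy_g45 = bool(had_endoscopy_g45)


def _parse_codes(cell, cast=str) -> set:
    if isinstance(cell, (set, frozenset, list, tuple)):
        return {cast(c) for c in cell if str(c) != ""}
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return set()
    return {cast(c) for c in str(cell).split(";") if c != ""}


def _code_sets(cohort: pd.DataFrame):
    sr = cohort["self_report_codes"].map(lambda c: _parse_codes(c, int))
    icd = cohort["icd10_codes"].map(_parse_codes)
    opcs = cohort["opcs4_codes"].map(_parse_codes)
    return sr, icd, opcs


def derive_primary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Primary case/control status from the three code families."""
    sr, icd, opcs = _code_sets(cohort)
    is_case = (
        sr.map(lambda s: bool(s & SELF_REPORT_CASE))
        | icd.map(lambda s: bool(s & ICD10_CASE))
        | opcs.map(lambda s: bool(s & OPCS4_SURGERY))
    )
    return pd.DataFrame(
        {"id": cohort["iid"] if "iid" in cohort.columns else cohort.index,
         "primary_status": is_case.map({True: CASE, False: CONTROL}).to_numpy()}
    )


def derive_sensitivity(
    cohort: pd.DataFrame, status: pd.DataFrame, level: int
) -> pd.Series:
    """One sensitivity-analysis status column given the primary statuses.

    Levels build on each other: SA1 drops self-report-only cases and
    at-risk controls; SA2 further requires the K21.0 code in cases; SA3
    requires anti-reflux surgery plus independent confirmation.
    """
    if level not in (1, 2, 3):
        raise ValueError("sensitivity level must be 1, 2 or 3")
    sr, icd, opcs = _code_sets(cohort)
    primary_case = (status["primary_status"] == CASE).to_numpy()

    hosp_evidence = (
        icd.map(lambda s: bool(s & ICD10_CASE))
        | opcs.map(lambda s: bool(s & OPCS4_SURGERY))
    ).to_numpy()
    control_at_risk = (
        cohort["on_acid_suppressant"].astype(bool)
        | cohort["had_endoscopy_g45"].astype(bool)
    ).to_numpy()

    sa1_case = primary_case & hosp_evidence
    sa1_excl = (primary_case & ~hosp_evidence) | (~primary_case & control_at_risk)

    if level == 1:
        case, excl = sa1_case, sa1_excl
    else:
        erosive = icd.map(lambda s: bool(s & ICD10_EROSIVE)).to_numpy()
        sa2_case = sa1_case & erosive
        sa2_excl = sa1_excl | (sa1_case & ~erosive)
        if level == 2:
            case, excl = sa2_case, sa2_excl
        else:
            # SA2-eligible cases retained only with anti-reflux surgery
            # plus at least one other confirming code
            surgery = opcs.map(lambda s: bool(s & OPCS4_SURGERY)).to_numpy()
            confirm = (
                sr.map(lambda s: bool(s & SELF_REPORT_CASE))
                | icd.map(lambda s: bool(s & ICD10_CASE))
            ).to_numpy()
            sa3_case = sa2_case & surgery & confirm
            sa3_excl = sa2_excl | (sa2_case & ~(surgery & confirm))
            case, excl = sa3_case, sa3_excl

    out = pd.Series(CONTROL, index=status.index, name=f"sa{level}_status")
    out[excl] = EXCLUDED
    out[case] = CASE
    return out


def derive_all(cohort: pd.DataFrame) -> pd.DataFrame:
    """Primary plus all three sensitivity statuses in one table."""
    status = derive_primary(cohort)
    for level in (1, 2, 3):
        status[f"sa{level}_status"] = derive_sensitivity(cohort, status, level)
    return status


def tabulate_flowchart(status: pd.DataFrame) -> pd.DataFrame:
    """Nested case/control/excluded counts per definition.

    Raises if the case counts fail the required nesting
    (SA3 <= SA2 <= SA1 <= primary).
    """
    rows = []
    for col, label in [
        ("primary_status", "primary"),
        ("sa1_status", "sensitivity_1"),
        ("sa2_status", "sensitivity_2"),
        ("sa3_status", "sensitivity_3"),
    ]:
        if col not in status.columns:
            continue
        vc = status[col].value_counts()
        rows.append(
            {
                "definition": label,
                "cases": int(vc.get(CASE, 0)),
                "controls": int(vc.get(CONTROL, 0)),
                "excluded": int(vc.get(EXCLUDED, 0)),
            }
        )
    report = pd.DataFrame(rows)
    cases = report["cases"].tolist()
    if any(b > a for a, b in zip(cases, cases[1:])):
        raise AssertionError(f"case counts are not nested: {cases}")
    return report
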