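"""Bookkeeping for the discovery cohort's clinical table.

The packaged table transcribes the published clinicopathological features
of the 23 MDS-with-excess-blasts patients who received azacitidine before
stem cell transplantation. Response classification follows the modified
IWG criteria as applied in the study: complete remission (CR) or marrow
CR (with or without hematologic improvement) counts as a responder;
primary disease progression or stable disease without hematologic
improvement counts as a non-responder.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .containers import NON_RESPONDER, RESPONDER, PhenotypeTable

__all__ = [
    "load_clinical_table",
    "classify_response",
    "summarize_cohort",
    "clinical_phenotypes",
]


def load_clinical_table() -> pd.DataFrame:
    """The packaged 23-patient clinical table, one row per patient."""
    path = resources.files("azasig").joinpath("data/clinical_table.tsv")
    with resources.as_file(path) as fp:
        df = pd.read_csv(fp, sep="\t", comment="#", dtype={"patient": str})
    return df.set_index("patient")


def classify_response(response: str) -> str:
    """Map a printed response code to responder / non-responder."""
    code = response.strip()
    if code.startswith("CR") or code.startswith("mCR"):
        return RESPONDER
    if code.startswith("primary DP") or code == "SD-HI":
        return NON_RESPONDER
    raise ValueError(f"unrecognized response code {code!r}")


def summarize_cohort(table: pd.DataFrame | None = None) -> dict[str, float]:
    """Headline counts of the clinical table under the responder definition."""
    df = load_clinical_table() if table is None else table
    groups = df["response"].map(classify_response)
    n = len(df)
    n_resp = int((groups == RESPONDER).sum())
    n_nonresp = int((groups == NON_RESPONDER).sum())
    n_aml = int((df["response"] == "primary DP to AML").sum())
    return {
        "n_patients": n,
        "n_responders": n_resp,
        "n_nonresponders": n_nonresp,
        "pct_responders": round(100.0 * n_resp / n, 1),
        "pct_nonresponders": round(100.0 * n_nonresp / n, 1),
        "n_primary_progression_to_aml": n_aml,
        "n_eb1": int((df["who_subtype"] == "MDS-EB-1").sum()),
        "n_eb2": int((df["who_subtype"] == "MDS-EB-2").sum()),
    }


def clinical_phenotypes(table: pd.DataFrame | None = None) -> PhenotypeTable:
    """The clinical table as a phenotype table with survival annotation."""
    df = load_clinical_table() if table is None else table
    frame = pd.DataFrame(
        {
            "group": df["response"].map(classify_response).to_numpy(),
            "time": df["survival_months"].to_numpy(dtype=float),
            "event": (df["status"] == "died").to_numpy(dtype=float),
        },
        index=pd.Index([f"P{p}" for p in df.index], name="sample_id"),
    )
    return PhenotypeTable(frame)
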