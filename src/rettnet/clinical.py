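"""Clinical severity tables, responder classification and demographics.

Severity is measured with the International Scoring System (ISS; lower is
less severe) at baseline (T1) and twelve months (T2).  A treated subject is
a responder when the ISS strictly decreases from T1 to T2; untreated
subjects carry no responder label.  Demographic summaries use the median
and Tukey-hinge interquartile range for age and the mean and sample (n-1)
standard deviation for ISS — the conventions that reproduce the published
group summaries from the individual-level reference table bundled with the
package (``load_reference_cohort``).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, RettNetError

CLINICAL_COLUMNS = ["subject_id", "group", "age", "iss_t1", "iss_t2"]


def load_reference_cohort() -> pd.DataFrame:
    """The bundled 18-patient demographic reference table (9 treated with
    IGF1, 9 untreated), transcribed from the study cohort: per-patient
    treatment group, age, follow-up, and ISS at baseline/12 months."""
    with resources.files("rettnet.data").joinpath("table1.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df = df.rename(columns={"patient_id": "subject_id",
                            "treatment": "group"})
    df["subject_id"] = df["subject_id"].astype(str)
    df["group"] = df["group"].str.lower()
    # the published responder column is kept verbatim for cross-checking;
    # classify_responders recomputes labels from the ISS values
    df["responder_published"] = df.pop("responder").replace(
        {"Responder": "responder", "Nonresponder": "nonresponder",
         "N/A": None})
    return df


def read_clinical_table(path: str | Path, sep: str | None = None
                        ) -> pd.DataFrame:
    """Read a delimited clinical table with columns subject_id, group, age,
    iss_t1, iss_t2 (extra columns are preserved)."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"clinical table {path} missing columns {missing}")
    df["subject_id"] = df["subject_id"].astype(str)
    if df["subject_id"].duplicated().any():
        raise FormatError("subject ids must be unique")
    return df


def write_clinical_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df.to_csv(path, sep=sep, index=False)
    return path


def classify_responders(ct: pd.DataFrame) -> pd.DataFrame:
    """Label treated subjects by clinical response: responder iff the ISS
    strictly decreased from baseline to twelve months (equal scores are
    nonresponse).  Untreated subjects receive a null label.  Deterministic
    and row-order invariant."""
    out = ct.copy()
    treated = out["group"].str.lower() == "treated"
    iss = out.loc[treated, ["iss_t1", "iss_t2"]]
    if iss.isna().any().any():
        bad = out.loc[treated][iss.isna().any(axis=1)]["subject_id"].tolist()
        raise RettNetError(
            f"treated subject(s) {bad} missing ISS scores; cannot classify")
    labels = np.where(out.loc[treated, "iss_t2"] < out.loc[treated, "iss_t1"],
                      "responder", "nonresponder")
    out["responder"] = None
    out.loc[treated, "responder"] = labels
    return out


def tukey_hinges(x) -> tuple[float, float]:
    """Lower and upper hinges: medians of the median-inclusive lower and
    upper halves of the sorted sample."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n == 0:
        raise RettNetError("empty sample")
    half = (n + 1) // 2  # include the median in both halves when n is odd
    return float(np.median(x[:half])), float(np.median(x[n - half:]))


def hinge_iqr(x) -> float:
    lo, hi = tukey_hinges(x)
    return hi - lo


@dataclass
class CohortSummary:
    """Demographic summary per group and overall."""

    table: pd.DataFrame  # index: group labels + "overall"

    def summary(self) -> str:
        return ("Cohort summary (age: median [hinge IQR]; ISS: mean +/- "
                "sample SD)\n" + self.table.to_string(
                    float_format=lambda v: f"{v:.1f}"))


def summarize(ct: pd.DataFrame) -> CohortSummary:
    """Median age with Tukey-hinge IQR, ISS mean with sample SD, and
    responder counts, per group and overall."""
    if len(ct) == 0:
        raise RettNetError("empty clinical table")
    ct = ct.copy()
    ct["group"] = ct["group"].str.lower()

    def one(sub: pd.DataFrame) -> dict:
        row = {
            "n": len(sub),
            "age_median": float(np.median(sub["age"])),
            "age_iqr": hinge_iqr(sub["age"]),
            "iss_t1_mean": float(np.mean(sub["iss_t1"])),
            "iss_t1_sd": float(np.std(sub["iss_t1"], ddof=1))
            if len(sub) > 1 else np.nan,
        }
        if "responder" in sub.columns:
            row["n_responders"] = int((sub["responder"] == "responder").sum())
            row["n_nonresponders"] = int(
                (sub["responder"] == "nonresponder").sum())
        return row

    rows = {grp: one(sub) for grp, sub in ct.groupby("group")}
    rows["overall"] = one(ct)
    return CohortSummary(table=pd.DataFrame(rows).T)
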