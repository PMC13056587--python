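"""Convergence of high-risk features within the high-genomic-complexity
(HGC) subgroup.

Multivariate survival modelling attenuates the prognostic value of HGC
once TP53 aberration, IGHV status, telomere length and epitype enter the
model; this module quantifies how far those four adverse features already
account for the HGC patients. Each HGC case is flagged for TP53 aberration,
U-CLL, short telomeres (TL-S) and the naive-like epitype (n-CLL), and the
summary partitions the subgroup into TP53-aberrant cases, TP53-wild-type
cases carrying at least one other adverse feature, and cases with none.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

FLAG_NAMES = ("TP53_ABERRANT", "U_CLL", "TL_S", "N_CLL")


@dataclass(frozen=True)
class HighRiskProfile:
    sample_id: str
    flags: frozenset
    missing: frozenset  # inputs that were unavailable, not negative

    @property
    def n_flags(self) -> int:
        return len(self.flags)


@dataclass(frozen=True)
class ConvergenceSummary:
    n_hgc: int
    n_tp53_aberrant: int
    n_tp53_wt_with_other_feature: int
    n_no_feature: int
    n_no_feature_with_missing: int  # flag-negative cases with unmeasured inputs
    cooccurrence: dict = field(default_factory=dict, hash=False, compare=False)

    @property
    def proportion_any_feature(self) -> float:
        """Percent of HGC cases carrying at least one high-risk feature."""
        return 100.0 * (self.n_hgc - self.n_no_feature) / self.n_hgc


def highrisk_flags(record: pd.Series | dict) -> HighRiskProfile:
    """High-risk flags of one integrated patient record.

    A missing input (IGHV, TL class or epitype not measured) leaves the
    flag absent but is tracked in ``missing`` so that "no high-risk
    feature" is never conflated with "not measured".
    """
    get = record.get if hasattr(record, "get") else record.__getitem__
    flags = set()
    missing = set()
    if bool(get("tp53_aberrant", False)):
        flags.add("TP53_ABERRANT")
    ighv = get("ighv", None)
    if ighv is None or (isinstance(ighv, float) and pd.isna(ighv)):
        missing.add("U_CLL")
    elif str(ighv) == "U-CLL":
        flags.add("U_CLL")
    tl = get("tl_class", None)
    if tl is None or (isinstance(tl, float) and pd.isna(tl)):
        missing.add("TL_S")
    elif str(tl) == "S":
        flags.add("TL_S")
    epi = get("epitype", None)
    if epi is None or (isinstance(epi, float) and pd.isna(epi)):
        missing.add("N_CLL")
    elif str(epi) == "n-CLL":
        flags.add("N_CLL")
    sid = get("sample_id", None) or getattr(record, "name", "")
    return HighRiskProfile(
        sample_id=str(sid), flags=frozenset(flags), missing=frozenset(missing)
    )


def profile_frame(cohort: pd.DataFrame, restrict: str | None = "HGC") -> pd.DataFrame:
    """Per-patient flag table (one boolean column per high-risk feature)."""
    df = cohort
    if restrict is not None:
        df = cohort[cohort["gc_class"] == restrict]
    if df.empty:
        return pd.DataFrame(
            columns=[*FLAG_NAMES, "n_flags", "n_missing_inputs"],
            index=pd.Index([], name="sample_id"),
        )
    rows = []
    for sid, rec in df.iterrows():
        prof = highrisk_flags(rec)
        rows.append(
            {
                "sample_id": str(sid),
                **{f: f in prof.flags for f in FLAG_NAMES},
                "n_flags": prof.n_flags,
                "n_missing_inputs": len(prof.missing),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def convergence_summary(
    cohort: pd.DataFrame, restrict: str | None = "HGC"
) -> ConvergenceSummary:
    """Partition the (by default HGC) subgroup by high-risk feature burden.

    The three counts — TP53-aberrant, TP53-wild-type with at least one of
    U-CLL / TL-S / n-CLL, and no feature at all — always partition the
    subgroup. A co-occurrence breakdown of flag combinations among the
    TP53-aberrant cases is attached for reporting.
    """
    prof = profile_frame(cohort, restrict=restrict)
    n = len(prof)
    if n == 0:
        warnings.warn("no patients in the restricted subgroup; empty summary")
        return ConvergenceSummary(0, 0, 0, 0, 0, {})
    tp53 = prof["TP53_ABERRANT"]
    other = prof[["U_CLL", "TL_S", "N_CLL"]].any(axis=1)
    n_tp53 = int(tp53.sum())
    n_wt_other = int((~tp53 & other).sum())
    n_none = int((~tp53 & ~other).sum())
    n_none_missing = int((~tp53 & ~other & (prof["n_missing_inputs"] > 0)).sum())
    co: dict[str, int] = {}
    aberrant = prof[tp53]
    others = ("U_CLL", "TL_S", "N_CLL")
    for k in range(len(others), -1, -1):
        for combo in combinations(others, k):
            mask = pd.Series(True, index=aberrant.index)
            for f in others:
                mask &= aberrant[f] if f in combo else ~aberrant[f]
            if int(mask.sum()):
                co["+".join(("TP53_ABERRANT",) + combo)] = int(mask.sum())
    return ConvergenceSummary(
        n_hgc=n,
        n_tp53_aberrant=n_tp53,
        n_tp53_wt_with_other_feature=n_wt_other,
        n_no_feature=n_none,
        n_no_feature_with_missing=n_none_missing,
        cooccurrence=co,
    )


def upset_table(cohort: pd.DataFrame, restrict: str | None = "HGC") -> pd.DataFrame:
    """Upset-style counts of every observed flag combination."""
    prof = profile_frame(cohort, restrict=restrict)
    if prof.empty:
        return pd.DataFrame(columns=["combination", "count"])
    combo = prof[list(FLAG_NAMES)].apply(
        lambda r: "+".join([f for f in FLAG_NAMES if r[f]]) or "(none)", axis=1
    )
    out = combo.value_counts().rename_axis("combination").reset_index(name="count")
    return out
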