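"""Per-patient molecular profile integration.

Combines the curation summary with targeted-sequencing mutation calls over
the nine-gene consensus panel, telomere length (TL), IGHV status and the
DNA-methylation epitype into one record per patient. Derived fields: gene
lesion states (wildtype / mutated / deleted / biallelic), TP53 aberration
(any TP53 hit), TL class (short / intermediate / long at the established
2.92 and 3.57 kb cut-offs) and tumour mutation burden over the panel.

Missing optional inputs (IGHV, epitype, TL) are kept as missing and
excluded per-analysis downstream; nothing is imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

#: consensus panel of recurrently mutated CLL genes
GENE_PANEL = (
    "ATM",
    "SF3B1",
    "NOTCH1",
    "TP53",
    "BIRC3",
    "XPO1",
    "MYD88",
    "SAMHD1",
    "MED12",
)

#: genes with a mapped deletion locus in the curation summary
GENE_DELETION_FLAG = {"TP53": "del17p", "ATM": "del11q", "BIRC3": "birc3_del"}


class GeneStateKind(str, Enum):
    WILDTYPE = "WILDTYPE"
    MUTATED = "MUTATED"
    DELETED = "DELETED"
    BIALLELIC = "BIALLELIC"


@dataclass(frozen=True)
class MutationCall:
    sample_id: str
    gene: str
    vaf: float | None = None
    consequence: str = ""

    def __post_init__(self) -> None:
        if self.gene not in GENE_PANEL:
            raise ValidationError(f"gene {self.gene!r} not in the consensus panel")
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise ValidationError(f"VAF {self.vaf} outside [0, 1]")


@dataclass(frozen=True)
class TLThresholds:
    """Established telomere-length cut-offs in kb."""

    short_max_kb: float = 2.92
    long_min_kb: float = 3.57

    def __post_init__(self) -> None:
        if not self.short_max_kb < self.long_min_kb:
            raise ValidationError("short_max_kb must be below long_min_kb")


def derive_gene_state(
    gene: str,
    has_mutation: bool,
    lesion_flags: Mapping[str, bool],
) -> GeneStateKind:
    """Lesion state of one gene from mutation and deletion evidence.

    Deletion evidence comes from the curation flags (TP53 via del17p, ATM
    via del11q, BIRC3 via its own deletion flag); a deletion plus a
    mutation — or a biallelic deletion at 13q14 handled separately — is a
    biallelic hit.
    """
    flag = GENE_DELETION_FLAG.get(gene)
    if flag is None:
        if gene not in GENE_PANEL:
            raise ConfigurationError(f"gene {gene!r} has no mapped deletion locus")
        has_deletion = False
    else:
        has_deletion = bool(lesion_flags.get(flag, False))
    if has_mutation and has_deletion:
        return GeneStateKind.BIALLELIC
    if has_mutation:
        return GeneStateKind.MUTATED
    if has_deletion:
        return GeneStateKind.DELETED
    return GeneStateKind.WILDTYPE


def tp53_aberration(state: GeneStateKind) -> bool:
    """TP53 aberration: copy-number loss, mutation or both."""
    return state is not GeneStateKind.WILDTYPE


def classify_tl(tl_kb: float, thresholds: TLThresholds = TLThresholds()) -> str:
    """TL class: 'S' below 2.92 kb, 'I' on the closed interval
    [2.92, 3.57] kb, 'L' above 3.57 kb."""
    if not tl_kb > 0:
        raise ValidationError("telomere length must be positive")
    if tl_kb < thresholds.short_max_kb:
        return "S"
    if tl_kb <= thresholds.long_min_kb:
        return "I"
    return "L"


def compute_tmb(mutations: Iterable[MutationCall] | int) -> tuple[int, str]:
    """Tumour mutation burden over the 9-gene panel and its reporting bin
    ('0', '1', '2', '>=3')."""
    if isinstance(mutations, int):
        count = mutations
        if count < 0:
            raise ValidationError("mutation count cannot be negative")
    else:
        count = sum(1 for _ in mutations)
    bin_label = str(count) if count < 3 else ">=3"
    return count, bin_label


def read_mutations(path) -> list[MutationCall]:
    """Mutation TSV (sample, gene, optional vaf/consequence) -> calls."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    calls = []
    for row in df.itertuples(index=False):
        vaf = getattr(row, "vaf", None)
        if vaf is not None and pd.isna(vaf):
            vaf = None
        calls.append(
            MutationCall(
                sample_id=str(row.sample),
                gene=str(row.gene),
                vaf=float(vaf) if vaf is not None else None,
                consequence=str(getattr(row, "consequence", "")),
            )
        )
    return calls


def build_cohort_table(
    clinical: pd.DataFrame,
    curation_summary: pd.DataFrame,
    mutations: Sequence[MutationCall],
    tl: pd.DataFrame | None = None,
    epitype: pd.DataFrame | None = None,
    tl_thresholds: TLThresholds = TLThresholds(),
) -> pd.DataFrame:
    """Assemble the integrated cohort table, one row per patient.

    ``clinical`` must carry a ``sample_id`` column (or index) with trial,
    age, sex, binet, ighv and the survival columns; ``curation_summary``
    is the per-sample output of :func:`gcx.segments.curate_cohort`.
    Samples with curated CNA data but no clinical row are an error (the
    join must be auditable); optional tables may cover a subset.
    """
    clin = clinical.copy()
    if "sample_id" in clin.columns:
        clin = clin.set_index("sample_id")
    clin.index = clin.index.astype(str)
    cur = curation_summary.copy()
    cur.index = cur.index.astype(str)
    orphans = sorted(set(cur.index) - set(clin.index))
    if orphans:
        raise ValidationError(
            f"samples with segments but no clinical row: {orphans[:10]}"
            + ("..." if len(orphans) > 10 else "")
        )
    df = clin.join(cur, how="left")
    # a clinical sample with no curated row had no detectable CNA at all
    if "cna_count" in df.columns:
        df["cna_count"] = df["cna_count"].fillna(0).astype(int)
        df["gc_class"] = df["gc_class"].fillna("LGC")
    for flag in ("del17p", "del11q", "del13q_mono", "del13q_biallelic", "tri12", "birc3_del"):
        if flag in df.columns:
            df[flag] = df[flag].map(lambda v: bool(v) if pd.notna(v) else False)

    # mutations -> per-gene indicator + TMB
    mut_by_sample: dict[str, set[str]] = {}
    for m in mutations:
        mut_by_sample.setdefault(m.sample_id, set()).add(m.gene)
    for gene in GENE_PANEL:
        df[f"{gene}_mut"] = [
            gene in mut_by_sample.get(s, set()) for s in df.index
        ]
    df["tmb"] = [len(mut_by_sample.get(s, set())) for s in df.index]
    df["tmb_bin"] = [compute_tmb(int(t))[1] for t in df["tmb"]]

    if tl is not None:
        t = tl.copy()
        if "sample_id" in t.columns:
            t = t.set_index("sample_id")
        elif "sample" in t.columns:
            t = t.set_index("sample")
        t.index = t.index.astype(str)
        df = df.join(t[["tl_kb"]], how="left")
    if "tl_kb" not in df.columns:
        df["tl_kb"] = np.nan
    df["tl_class"] = [
        classify_tl(v, tl_thresholds) if pd.notna(v) else None for v in df["tl_kb"]
    ]

    if epitype is not None:
        e = epitype.copy()
        if "sample_id" in e.columns:
            e = e.set_index("sample_id")
        elif "sample" in e.columns:
            e = e.set_index("sample")
        e.index = e.index.astype(str)
        df = df.join(e[["epitype"]], how="left", rsuffix="_ep")
        if "epitype_ep" in df.columns:
            df["epitype"] = df.pop("epitype_ep")
    if "epitype" not in df.columns:
        df["epitype"] = None

    # gene lesion states for the genes with a mapped deletion locus
    for gene, flag in GENE_DELETION_FLAG.items():
        states = []
        for s in df.index:
            row_flags = {flag: bool(df.at[s, flag]) if flag in df.columns and pd.notna(df.at[s, flag]) else False}
            states.append(
                derive_gene_state(gene, bool(df.at[s, f"{gene}_mut"]), row_flags).value
            )
        df[f"{gene}_state"] = states
    # any 13q14 deletion, mono- or biallelic
    if "del13q_biallelic" in df.columns:
        df["del13q"] = df["del13q_mono"] | df["del13q_biallelic"]
    df["tp53_aberrant"] = [
        tp53_aberration(GeneStateKind(s)) for s in df["TP53_state"]
    ]
    return df


def data_dictionary() -> dict[str, str]:
    """Field definitions of the integrated cohort table."""
    return {
        "trial": "clinical trial label (CLL4, ARC, ADM)",
        "age": "age at randomization, years",
        "sex": "patient sex",
        "binet": "Binet stage A/B/C",
        "ighv": "IGHV mutational status: U-CLL (unmutated) or M-CLL",
        "epitype": "DNA-methylation epitype: n-CLL, i-CLL or m-CLL",
        "tl_kb": "telomere length, kb",
        "tl_class": "TL class: S (<2.92 kb), I (2.92-3.57 kb), L (>3.57 kb)",
        "cna_count": "curated CNA count (biallelic losses count twice)",
        "gc_class": "genomic complexity: LGC 0-2, IGC 3-4, HGC >=5 CNAs",
        "tmb": "mutation count over the 9-gene consensus panel",
        "tmb_bin": "TMB reporting bin: 0, 1, 2, >=3",
        "tp53_aberrant": "TP53 copy-number loss, mutation or both",
        "del17p": "loss overlapping the TP53 locus",
        "del11q": "loss overlapping the ATM locus",
        "del13q": "any 13q14 deletion (mono- or biallelic)",
        "del13q_biallelic": "biallelic 13q14 deletion",
        "tri12": "trisomy 12 (whole-chromosome-12 gain)",
        "birc3_del": "loss overlapping the BIRC3 locus",
    }
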