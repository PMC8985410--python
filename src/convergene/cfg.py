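"""Convergent Functional Genomics (CFG) scoring.

CFG prioritizes candidate genes by counting, per gene, how many of five
independent lines of Alzheimer's-disease evidence are present:

1. genetic association  — at least one GWAS locus significantly associated,
2. eQTL                 — at least one AD-risk expression QTL,
3. PPI                  — physical interaction with an AD core gene
                          (APP, PSEN1, PSEN2, APOE or MAPT),
4. pathology correlate  — expression correlated with amyloid-beta or Tau
                          pathology in AD mouse models (either marker
                          significant suffices),
5. early alteration     — differential expression in the hippocampus of
                          2-month-old AD mice.

Each satisfied criterion contributes one point, so the score is an integer
in 0..5 with 5 the highest priority.  A missing (NA) value in any channel
counts as absence of evidence for that channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: The five AD core genes used for the protein-protein interaction criterion.
AD_CORE_GENES = frozenset({"APP", "PSEN1", "PSEN2", "APOE", "MAPT"})

#: Valid significance markers for the pathology correlations.  ``ns`` is
#: "not significant"; the others encode increasing star levels.
SIG_LEVELS = ("ns", "p05", "p01", "p001")

CRITERIA = (
    "genetic_association",
    "eqtl",
    "ppi",
    "pathology_cor",
    "early_alteration",
)


@dataclass(frozen=True)
class GeneEvidence:
    """Five-channel evidence for one gene.

    ``eqtl_count`` and ``gwas_locus_count`` are non-negative counts or
    ``None`` (NA).  ``ppi_core_partners`` is the subset of AD core genes the
    gene physically interacts with.  ``early_deg`` is "yes", "no" or ``None``.
    ``abeta_cor`` / ``tau_cor`` are ``(r, sig)`` pairs with ``sig`` one of
    :data:`SIG_LEVELS`, or ``None`` when unmeasured.
    """

    gene: str
    eqtl_count: int | None = None
    gwas_locus_count: int | None = None
    ppi_core_partners: frozenset[str] = frozenset()
    early_deg: str | None = None
    abeta_cor: tuple[float, str] | None = None
    tau_cor: tuple[float, str] | None = None

    def __post_init__(self) -> None:
        extra = set(self.ppi_core_partners) - AD_CORE_GENES
        if extra:
            raise ValueError(
                f"{self.gene}: PPI partners must be AD core genes, got {sorted(extra)}"
            )
        for name, cor in (("abeta_cor", self.abeta_cor), ("tau_cor", self.tau_cor)):
            if cor is not None and cor[1] not in SIG_LEVELS:
                raise ValueError(
                    f"{self.gene}: {name} significance flag {cor[1]!r} "
                    f"not one of {SIG_LEVELS}"
                )


def _significant(cor: tuple[float, str] | None) -> bool:
    return cor is not None and cor[1] != "ns"


def score_gene(evidence: GeneEvidence) -> dict:
    """Score one gene: a boolean per criterion plus their integer sum.

    NA in a channel never contributes a point.
    """
    bits = {
        "genetic_association": bool(
            evidence.gwas_locus_count is not None and evidence.gwas_locus_count > 0
        ),
        "eqtl": bool(evidence.eqtl_count is not None and evidence.eqtl_count > 0),
        "ppi": len(evidence.ppi_core_partners) > 0,
        "pathology_cor": _significant(evidence.abeta_cor)
        or _significant(evidence.tau_cor),
        "early_alteration": evidence.early_deg == "yes",
    }
    bits["score"] = sum(bits[c] for c in CRITERIA)
    bits["gene"] = evidence.gene
    return bits


def score_table(evidence: list[GeneEvidence] | pd.DataFrame) -> pd.DataFrame:
    """Score a whole evidence table, preserving input row order.

    Accepts either a list of :class:`GeneEvidence` or a DataFrame in the
    evidence-TSV schema (see :func:`evidence_from_frame`).  Duplicate gene
    ids are permitted and scored independently.
    """
    if isinstance(evidence, pd.DataFrame):
        evidence = evidence_from_frame(evidence)
    if len(evidence) == 0:
        return pd.DataFrame(columns=["gene", *CRITERIA, "score"])
    rows = [score_gene(ev) for ev in evidence]
    return pd.DataFrame(rows, columns=["gene", *CRITERIA, "score"])


def prioritize(cfg_result: pd.DataFrame, min_score: int = 4) -> pd.DataFrame:
    """Genes with score >= ``min_score``, sorted by score descending.

    Ties keep input order (stable sort), matching the convention that the
    top candidates are the genes attaining the maximum score.
    """
    kept = cfg_result[cfg_result["score"] >= min_score]
    return kept.sort_values("score", ascending=False, kind="stable").reset_index(
        drop=True
    )


def _parse_partners(raw: str) -> frozenset[str]:
    raw = str(raw).strip()
    if raw in ("-", "", "nan", "NA"):
        return frozenset()
    return frozenset(p.strip() for p in raw.split(";") if p.strip())


def _parse_count(raw) -> int | None:
    if pd.isna(raw) or str(raw).strip() in ("NA", ""):
        return None
    return int(raw)


def evidence_from_frame(frame: pd.DataFrame) -> list[GeneEvidence]:
    """Convert an evidence TSV DataFrame to :class:`GeneEvidence` rows.

    Expected columns: gene, eqtl_count, gwas_count, ppi_partners,
    early_deg, abeta_r, abeta_sig, tau_r, tau_sig.  "-" denotes an empty
    partner set, "NA" a missing value.
    """
    out = []
    for _, row in frame.iterrows():
        early = str(row["early_deg"]).strip()
        abeta = (
            None
            if pd.isna(row["abeta_r"])
            else (float(row["abeta_r"]), str(row["abeta_sig"]).strip())
        )
        tau = (
            None
            if pd.isna(row["tau_r"])
            else (float(row["tau_r"]), str(row["tau_sig"]).strip())
        )
        out.append(
            GeneEvidence(
                gene=str(row["gene"]),
                eqtl_count=_parse_count(row["eqtl_count"]),
                gwas_locus_count=_parse_count(row["gwas_count"]),
                ppi_core_partners=_parse_partners(row["ppi_partners"]),
                early_deg=None if early in ("NA", "nan", "") else early,
                abeta_cor=abeta,
                tau_cor=tau,
            )
        )
    return out
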