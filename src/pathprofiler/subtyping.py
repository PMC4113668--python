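"""Clinical-first breast-cancer subtype assignment.

Tumor samples are assigned to luminal A, luminal B, triple-negative or
HER2+ by a decision cascade that mirrors clinical practice: HER2 assay
results (IHC, with FISH adjudicating equivocal IHC) take precedence,
ER-positive samples are then split into luminal A/B by their PAM50 call,
triple-negatives are extracted from the ER-negative pool by PR status,
and PAM50 alone is the fallback when ER or HER2 status is unavailable.
Samples the rules cannot place are reported as Unclassified, never
guessed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "ClinicalRecord",
    "SubtypeCall",
    "SUBTYPES",
    "classify_sample",
    "classify_cohort",
    "read_clinical_tsv",
    "write_clinical_tsv",
    "write_subtype_calls",
]

SUBTYPES = ("LuminalA", "LuminalB", "TripleNegative", "HER2pos")

_IHC = {"positive", "negative", "missing"}
_HER2_IHC = {"positive", "negative", "equivocal", "missing"}
_PAM50 = {"LumA", "LumB", "Her2", "Basal", "Normal", "missing"}
_PAM50_FALLBACK = {
    "LumA": "LuminalA",
    "LumB": "LuminalB",
    "Her2": "HER2pos",
    "Basal": "TripleNegative",
    "Normal": "Unclassified",
}


@dataclass(frozen=True)
class ClinicalRecord:
    """IHC/FISH receptor status plus PAM50 call for one tumor sample.

    ``pr_ihc`` also carries expression-based PR calls when a cohort lacks
    the IHC assay; the cascade does not distinguish the two sources.
    """

    sample_id: str
    er_ihc: str = "missing"
    pr_ihc: str = "missing"
    her2_ihc: str = "missing"
    her2_fish: str = "missing"
    pam50: str = "missing"

    def __post_init__(self) -> None:
        for name, value, allowed in (
            ("er_ihc", self.er_ihc, _IHC),
            ("pr_ihc", self.pr_ihc, _IHC),
            ("her2_ihc", self.her2_ihc, _HER2_IHC),
            ("her2_fish", self.her2_fish, _IHC),
            ("pam50", self.pam50, _PAM50),
        ):
            if value not in allowed:
                raise ValueError(f"{name}={value!r} not in {sorted(allowed)}")


@dataclass(frozen=True)
class SubtypeCall:
    sample_id: str
    subtype: str
    rule_fired: str


def _her2_status(record: ClinicalRecord) -> str:
    """Combined HER2 call: FISH adjudicates equivocal IHC."""
    if record.her2_ihc == "positive" or record.her2_fish == "positive":
        return "positive"
    if record.her2_ihc == "missing" and record.her2_fish == "missing":
        return "missing"
    # negative IHC, or equivocal IHC without positive FISH
    return "negative"


def classify_sample(record: ClinicalRecord) -> SubtypeCall:
    """Assign one sample to a subtype via the clinical-first cascade.

    Total: every record receives exactly one subtype (possibly
    Unclassified); records with no usable data yield Unclassified with
    ``rule_fired="no_data"`` rather than an exception.
    """
    sid = record.sample_id
    her2 = _her2_status(record)

    if her2 == "positive":
        return SubtypeCall(sid, "HER2pos", "her2_assay_positive")

    er = record.er_ihc
    # HER2 or ER missing: the assay cascade cannot run; fall back to PAM50.
    if her2 == "missing" or er == "missing":
        if record.pam50 != "missing":
            return SubtypeCall(sid, _PAM50_FALLBACK[record.pam50], "pam50_fallback")
        if er == "missing" and her2 == "missing" and record.pr_ihc == "missing":
            return SubtypeCall(sid, "Unclassified", "no_data")
        return SubtypeCall(sid, "Unclassified", "insufficient_data")

    if er == "positive":
        if record.pam50 == "LumA":
            return SubtypeCall(sid, "LuminalA", "er_positive_pam50_luma")
        if record.pam50 == "LumB":
            return SubtypeCall(sid, "LuminalB", "er_positive_pam50_lumb")
        return SubtypeCall(sid, "Unclassified", "er_positive_pam50_unresolved")

    # er negative
    if record.pr_ihc == "negative":
        return SubtypeCall(sid, "TripleNegative", "er_pr_her2_negative")
    if record.pr_ihc == "missing":
        return SubtypeCall(sid, "Unclassified", "er_negative_pr_missing")
    # ER-/PR+ non-HER2: the cascade assigns nothing; refuse to guess.
    return SubtypeCall(sid, "Unclassified", "er_negative_pr_positive")


def classify_cohort(records: Iterable[ClinicalRecord]):
    """Classify every record; return (calls, subtype -> sample id list).

    Unclassified samples appear in the calls with rule audit trails but
    are excluded from the per-subtype lists used downstream.  Duplicate
    sample ids raise ``ValueError``.
    """
    records = list(records)
    ids = [r.sample_id for r in records]
    if len(ids) != len(set(ids)):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample ids: {dup[:5]}")
    calls = [classify_sample(r) for r in records]
    by_subtype: dict = {s: [] for s in SUBTYPES}
    for call in calls:
        if call.subtype in by_subtype:
            by_subtype[call.subtype].append(call.sample_id)
    return calls, by_subtype


_TOKEN_MAP = {"": "missing", "na": "missing", "nan": "missing", "missing": "missing"}


def _token(value: str) -> str:
    v = value.strip()
    return _TOKEN_MAP.get(v.lower(), v)


def read_clinical_tsv(path) -> list:
    """Read a clinical table (sample_id, er_ihc, pr_ihc, her2_ihc, her2_fish, pam50)."""
    records = []
    with open(path, "rt", encoding="utf-8") as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                expected = ["sample_id", "er_ihc", "pr_ihc", "her2_ihc", "her2_fish", "pam50"]
                if header != expected:
                    raise ValueError(f"{path}: expected columns {expected}, got {header}")
                continue
            if len(fields) != 6:
                raise ValueError(f"{path}: expected 6 columns, got {len(fields)}")
            records.append(
                ClinicalRecord(
                    sample_id=fields[0].strip(),
                    er_ihc=_token(fields[1]),
                    pr_ihc=_token(fields[2]),
                    her2_ihc=_token(fields[3]),
                    her2_fish=_token(fields[4]),
                    pam50=_token(fields[5]),
                )
            )
    return records


def write_clinical_tsv(records: Iterable[ClinicalRecord], path, header_comment: str | None = None) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("sample_id\ter_ihc\tpr_ihc\ther2_ihc\ther2_fish\tpam50\n")
        for r in records:
            out = [r.sample_id] + [
                "" if v == "missing" else v
                for v in (r.er_ihc, r.pr_ihc, r.her2_ihc, r.her2_fish, r.pam50)
            ]
            fh.write("\t".join(out) + "\n")


def write_subtype_calls(calls: Iterable[SubtypeCall], path, header_comment: str | None = None) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("sample_id\tsubtype\trule_fired\n")
        for c in calls:
            fh.write(f"{c.sample_id}\t{c.subtype}\t{c.rule_fired}\n")
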