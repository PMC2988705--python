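"""Readers and writers for the external file formats.

Two concept-table dialects are supported: a pipe-delimited RRF-style table
(the full 18-column MRCONSO layout, and a compact 5-column ``SIMPLE5``
dialect with the same semantics used for fixtures) and a tab-delimited
SNOMED-style concept+description file pair.  Frequency tables are plain
CSV.  Reports are TSV.  All text is UTF-8.
"""

from __future__ import annotations

import csv
import warnings
from typing import Dict, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .model import Concept, FrequencyTable, SourceAtom, VocabularyView
from .textnorm import strip_paren_tag

__all__ = [
    "read_mrconso",
    "write_simple5",
    "read_snomed_descriptions",
    "read_frequency_table",
    "read_concept_metadata",
    "apply_metadata",
    "write_concept_metadata",
    "write_mapping_report",
    "read_mapping_report",
    "write_audit_report",
    "write_batch_results",
    "write_summary",
    "format_summary_text",
]

# Column indices in the two pipe-delimited dialects.
_UMLS18 = {"cui": 0, "sab": 11, "tty": 12, "code": 13, "str": 14, "ncols": 18}
_SIMPLE5 = {"cui": 0, "sab": 1, "tty": 2, "code": 3, "str": 4, "ncols": 5}

MAPPING_REPORT_COLUMNS = (
    "source_code",
    "source_term",
    "outcome",
    "target_ids",
    "pattern",
    "score",
)

AUDIT_REPORT_COLUMNS = ("kind", "evidence", "concept_ids", "sources")


def read_mrconso(
    path,
    dialect: str = "SIMPLE5",
    sab: Optional[str] = None,
) -> VocabularyView:
    """Read a pipe-delimited concept table into a :class:`VocabularyView`.

    One concept is produced per distinct CUI (within the ``sab`` filter if
    given).  The first PT or FN atom in file order becomes the preferred
    term; if a concept has neither, the first atom wins.  An empty file
    yields an empty view; a row with the wrong column count raises
    ``ValueError`` naming the line number.
    """
    try:
        layout = {"UMLS18": _UMLS18, "SIMPLE5": _SIMPLE5}[dialect.upper()]
    except KeyError:
        raise ValueError(f"unknown dialect {dialect!r}") from None

    atoms: Dict[str, List[SourceAtom]] = {}
    sources: Dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("|")
            # RRF rows conventionally end with a trailing '|'.
            if len(fields) == layout["ncols"] + 1 and fields[-1] == "":
                fields = fields[:-1]
            if len(fields) != layout["ncols"]:
                raise ValueError(
                    f"{path}: line {lineno}: expected {layout['ncols']} "
                    f"columns, found {len(fields)}"
                )
            row_sab = fields[layout["sab"]]
            if sab is not None and row_sab != sab:
                continue
            term = fields[layout["str"]].strip()
            if not term:
                raise ValueError(f"{path}: line {lineno}: empty term string")
            cui = fields[layout["cui"]]
            tty = fields[layout["tty"]].strip() or "SY"
            atoms.setdefault(cui, []).append(
                SourceAtom(cui, term, tty, row_sab)
            )
            sources.setdefault(cui, row_sab)

    view = VocabularyView(source=sab or "")
    for cui, cui_atoms in atoms.items():
        preferred = next(
            (a for a in cui_atoms if a.term_type in ("PT", "FN")), cui_atoms[0]
        )
        view.add(
            Concept(
                concept_id=cui,
                preferred_term=preferred.term,
                terms=list(cui_atoms),
                source=sources[cui],
            )
        )
    return view


def write_simple5(view: VocabularyView, path) -> None:
    """Serialize a view in the 5-column pipe dialect (CODE = concept id).

    The preferred atom is written first per concept so a round trip
    reproduces concept ids, preferred terms and the atom multiset.
    """
    with open(path, "w", encoding="utf-8") as handle:
        for concept in view:
            ordered = sorted(
                concept.terms,
                key=lambda a: (a.term != concept.preferred_term, ),
            )
            for atom in ordered:
                handle.write(
                    f"{concept.concept_id}|{atom.source or view.source}|"
                    f"{atom.term_type}|{concept.concept_id}|{atom.term}\n"
                )


def read_snomed_descriptions(concept_path, description_path) -> VocabularyView:
    """Read a tab-delimited SNOMED-style concept + description file pair.

    Only active concepts and active descriptions are retained.  The
    display form of a fully-specified name (FN) has its trailing
    parenthesized semantic tag stripped.  Descriptions pointing at unknown
    concept ids are skipped with a warning.
    """
    active: Set[str] = set()
    with open(concept_path, encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            if str(row["active"]).strip() == "1":
                active.add(row["id"].strip())

    atoms: Dict[str, List[SourceAtom]] = {}
    with open(description_path, encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            if str(row["active"]).strip() != "1":
                continue
            concept_id = row["conceptId"].strip()
            if concept_id not in active:
                warnings.warn(
                    f"description {row['id']} references unknown concept "
                    f"{concept_id}; skipped",
                    stacklevel=2,
                )
                continue
            term = row["term"].strip()
            if not term:
                continue
            tty = row["typeId"].strip().upper() or "SY"
            atoms.setdefault(concept_id, []).append(
                SourceAtom(concept_id, term, tty, "SNOMEDCT")
            )

    view = VocabularyView(source="SNOMEDCT")
    for concept_id in active:
        concept_atoms = atoms.get(concept_id)
        if not concept_atoms:
            continue
        preferred = next(
            (a for a in concept_atoms if a.term_type == "PT"),
            next((a for a in concept_atoms if a.term_type == "FN"), concept_atoms[0]),
        )
        display = (
            strip_paren_tag(preferred.term)
            if preferred.term_type == "FN"
            else preferred.term
        )
        view.add(
            Concept(
                concept_id=concept_id,
                preferred_term=display,
                terms=list(concept_atoms),
                source="SNOMEDCT",
            )
        )
    return view


def read_frequency_table(path) -> FrequencyTable:
    """Read a ``code,label,count`` CSV into a :class:`FrequencyTable`.

    Thousands separators in counts are tolerated ("1,204" -> 1204) and
    duplicate codes are summed.  Negative or non-numeric counts raise
    ``ValueError`` naming the line number.
    """
    table = FrequencyTable()
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle)
        header = next(reader, None)
        if header is None:
            return table
        for lineno, row in enumerate(reader, start=2):
            if not row or not any(cell.strip() for cell in row):
                continue
            if len(row) < 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns")
            code, label = row[0].strip(), row[1].strip()
            raw = row[2].strip().replace(",", "")
            try:
                count = int(raw)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric count {row[2]!r}"
                ) from None
            if count < 0:
                raise ValueError(f"{path}: line {lineno}: negative count {count}")
            table.add(code, count, label)
    return table


# ---------------------------------------------------------------------------
# concept metadata sidecar (categories + LLT->PT links)


def read_concept_metadata(path) -> Dict[str, Tuple[Optional[str], Tuple[str, ...]]]:
    """Read a ``concept_id,category,parent_ids`` CSV sidecar.

    ``parent_ids`` is semicolon-joined and may be empty; ``category`` may
    be empty.  Returns a mapping usable with :func:`apply_metadata`.
    """
    meta: Dict[str, Tuple[Optional[str], Tuple[str, ...]]] = {}
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle)
        for row in reader:
            category = (row.get("category") or "").strip() or None
            parents = tuple(
                p.strip()
                for p in (row.get("parent_ids") or "").split(";")
                if p.strip()
            )
            meta[row["concept_id"].strip()] = (category, parents)
    return meta


def apply_metadata(
    view: VocabularyView,
    meta: Dict[str, Tuple[Optional[str], Tuple[str, ...]]],
) -> VocabularyView:
    """Attach categories and parent links to a view, in place."""
    for concept_id, (category, parents) in meta.items():
        concept = view.get(concept_id)
        if concept is None:
            continue
        if category is not None:
            concept.category = category
        if parents:
            concept.parent_ids = parents
    return view


def write_concept_metadata(view: VocabularyView, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(["concept_id", "category", "parent_ids"])
        for concept in view:
            writer.writerow(
                [
                    concept.concept_id,
                    concept.category or "",
                    ";".join(concept.parent_ids),
                ]
            )


# ---------------------------------------------------------------------------
# reports


def write_mapping_report(results: Sequence, path) -> None:
    """Write mapping results as TSV, one row per result, input order kept.

    ``target_ids`` is semicolon-joined in target order; ``pattern`` is
    empty for results with no composition pattern.
    """
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(MAPPING_REPORT_COLUMNS) + "\n")
        for result in results:
            pattern = result.pattern if result.pattern not in ("NONE", None) else ""
            handle.write(
                "\t".join(
                    [
                        result.source_code,
                        result.source_term,
                        result.outcome,
                        ";".join(result.targets),
                        pattern,
                        f"{result.score:.6f}",
                    ]
                )
                + "\n"
            )


def read_mapping_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def write_audit_report(findings: Sequence, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(AUDIT_REPORT_COLUMNS) + "\n")
        for finding in findings:
            handle.write(
                "\t".join(
                    [
                        finding.kind,
                        finding.evidence,
                        ";".join(finding.concept_ids),
                        ";".join(finding.sources),
                    ]
                )
                + "\n"
            )


def write_batch_results(table: pd.DataFrame, path) -> None:
    """Write a batch-search table as TSV (score 6 dp, coverage 4 dp)."""
    out = table.copy()
    if "score" in out:
        out["score"] = out["score"].map(lambda v: f"{v:.6f}")
    if "coverage" in out:
        out["coverage"] = out["coverage"].map(lambda v: f"{v:.4f}")
    out.to_csv(path, sep="\t", index=False)


_SUMMARY_ROWS = (
    ("n_records", "A. Number of records in data set"),
    ("n_unique", "B. Unique preferred terms in data set"),
    ("n_mapped", "C. Unique terms already mapped to target terminology"),
    ("n_highfreq", "D. High-frequency terms (collectively >= share of records)"),
    ("n_highfreq_mapped", "E. High-frequency terms already mapped"),
    ("n_manual", "F. Number needing manual mapping (D-E)"),
)


def write_summary(summary, path) -> None:
    """Write a workload summary as a two-column TSV."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("field\tvalue\n")
        for field_name, _ in _SUMMARY_ROWS:
            value = getattr(summary, field_name)
            handle.write(f"{field_name}\t{'' if value is None else value}\n")
        for field_name in ("pct_mapped", "pct_highfreq", "pct_highfreq_mapped"):
            handle.write(f"{field_name}\t{getattr(summary, field_name)}\n")


def format_summary_text(summary) -> str:
    """Human-readable block mirroring the standard workload-table layout."""
    lines = []
    pct = {
        "n_mapped": summary.pct_mapped,
        "n_highfreq": summary.pct_highfreq,
        "n_highfreq_mapped": summary.pct_highfreq_mapped,
    }
    for field_name, label in _SUMMARY_ROWS:
        value = getattr(summary, field_name)
        if value is None:
            continue
        suffix = f" ({pct[field_name]}%)" if field_name in pct else ""
        lines.append(f"{label}\t{value}{suffix}")
    return "\n".join(lines)
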