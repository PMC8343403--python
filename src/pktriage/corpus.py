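"""Reading and writing PubMed/MEDLINE corpora and label tables.

A corpus is a list of :class:`DocumentRecord` objects holding the textual
fields and metadata lists of one PubMed citation each.  Labels live in a
separate two-column table keyed by PMID, with the positive class marking
publications that report newly estimated in-vivo pharmacokinetic
parameters ("Relevant").
"""

from __future__ import annotations

import gzip
import io
import json
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import IO, Iterable, Union

import pandas as pd
from lxml import etree

logger = logging.getLogger(__name__)

RELEVANT = "Relevant"
NOT_RELEVANT = "Not Relevant"

#: Metadata list/scalar fields available on a record, in reporting order.
FIELD_NAMES = (
    "title",
    "abstract",
    "authors",
    "journal",
    "publication_types",
    "keywords",
    "mesh_terms",
    "chemicals",
    "affiliations",
)


@dataclass
class DocumentRecord:
    """Textual fields and metadata of one PubMed citation."""

    pmid: str
    title: str
    abstract: str = ""
    authors: list[str] = field(default_factory=list)
    journal: str = ""
    publication_types: list[str] = field(default_factory=list)
    keywords: list[str] = field(default_factory=list)
    mesh_terms: list[str] = field(default_factory=list)
    chemicals: list[str] = field(default_factory=list)
    affiliations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValueError("DocumentRecord requires a non-empty pmid")
        if not self.title:
            raise ValueError(f"DocumentRecord {self.pmid!r} requires a non-empty title")


@dataclass(frozen=True)
class LabelledDocument:
    """A PMID together with its binary relevance label."""

    pmid: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in (RELEVANT, NOT_RELEVANT):
            raise ValueError(f"label must be {RELEVANT!r} or {NOT_RELEVANT!r}, got {self.label!r}")


def _normalise_label(raw: str) -> str:
    """Map a raw label string onto the two canonical values.

    Matching is case-insensitive with internal whitespace collapsed, so
    "Not Relevant", "not relevant" and "NotRelevant" are all equivalent.
    """
    key = re.sub(r"\s+", "", raw).lower()
    if key == "relevant":
        return RELEVANT
    if key in ("notrelevant", "irrelevant", "not-relevant"):
        return NOT_RELEVANT
    raise ValueError(f"unknown label {raw!r}")


# ---------------------------------------------------------------------------
# MEDLINE XML parsing

def _text(elem) -> str:
    """All text content of an element, markup stripped."""
    if elem is None:
        return ""
    return " ".join("".join(elem.itertext()).split())


def _open_xml(source: Union[str, Path, IO[bytes]]) -> IO[bytes]:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    path = Path(source)
    if path.suffix == ".gz":
        return gzip.open(path, "rb")
    return open(path, "rb")


def parse_pubmed_xml(source: Union[str, Path, IO[bytes], bytes]) -> list[DocumentRecord]:
    """Parse MEDLINE-dialect XML (baseline or updatefiles) into records.

    Structured abstracts (several AbstractText sections) are concatenated
    in document order separated by single spaces.  MeSH descriptor names
    are kept; qualifiers are dropped.  Citations without a PMID are
    skipped with a logged warning.  Malformed XML raises
    :class:`lxml.etree.XMLSyntaxError` carrying the offending position.
    """
    if isinstance(source, bytes):
        source = io.BytesIO(source)
    stream = _open_xml(source)
    try:
        tree = etree.parse(stream)
    except etree.XMLSyntaxError as exc:  # position info lives on the error
        raise etree.XMLSyntaxError(
            f"malformed MEDLINE XML: {exc.msg}", exc.code, exc.lineno, exc.offset
        ) from exc
    root = tree.getroot()

    records: list[DocumentRecord] = []
    skipped = 0
    for cit in root.iter("MedlineCitation"):
        pmid = _text(cit.find("PMID"))
        if not pmid:
            skipped += 1
            logger.warning("skipping citation without PMID")
            continue
        art = cit.find("Article")
        title = _text(art.find("ArticleTitle")) if art is not None else ""
        if not title:
            skipped += 1
            logger.warning("skipping citation %s without title", pmid)
            continue

        abstract = ""
        if art is not None:
            parts = [_text(t) for t in art.findall("Abstract/AbstractText")]
            abstract = " ".join(p for p in parts if p)

        authors = []
        if art is not None:
            for a in art.findall("AuthorList/Author"):
                last, fore = _text(a.find("LastName")), _text(a.find("ForeName"))
                coll = _text(a.find("CollectiveName"))
                name = f"{fore} {last}".strip() if (last or fore) else coll
                if name:
                    authors.append(name)

        journal = _text(art.find("Journal/Title")) if art is not None else ""
        pub_types = (
            [_text(t) for t in art.findall("PublicationTypeList/PublicationType")]
            if art is not None
            else []
        )
        affiliations = (
            [_text(t) for t in art.findall(".//AffiliationInfo/Affiliation")]
            if art is not None
            else []
        )
        keywords = [_text(k) for k in cit.findall("KeywordList/Keyword")]
        mesh = [_text(m) for m in cit.findall("MeshHeadingList/MeshHeading/DescriptorName")]
        chemicals = [_text(c) for c in cit.findall("ChemicalList/Chemical/NameOfSubstance")]

        records.append(
            DocumentRecord(
                pmid=pmid,
                title=title,
                abstract=abstract,
                authors=[a for a in authors if a],
                journal=journal,
                publication_types=[p for p in pub_types if p],
                keywords=[k for k in keywords if k],
                mesh_terms=[m for m in mesh if m],
                chemicals=[c for c in chemicals if c],
                affiliations=[a for a in affiliations if a],
            )
        )
    if skipped:
        logger.warning("skipped %d citation(s) lacking PMID or title", skipped)

    # updatefile semantics: a later record with the same PMID replaces the earlier one
    by_pmid: dict[str, DocumentRecord] = {}
    for rec in records:
        if rec.pmid in by_pmid:
            logger.warning("duplicate PMID %s: keeping the last record", rec.pmid)
        by_pmid[rec.pmid] = rec
    return list(by_pmid.values())


# ---------------------------------------------------------------------------
# Label tables

def read_labels(path: Union[str, Path, IO[str]]) -> list[LabelledDocument]:
    """Read a CSV label table with columns ``pmid`` and ``label``.

    Label strings are normalised to the canonical "Relevant" /
    "Not Relevant" values.  Unknown labels and duplicate PMIDs are hard
    errors naming the offending row.
    """
    df = pd.read_csv(path, dtype=str)
    for col in ("pmid", "label"):
        if col not in df.columns:
            raise ValueError(f"label table must have a {col!r} column; found {list(df.columns)}")
    out: list[LabelledDocument] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        try:
            label = _normalise_label(str(row["label"]))
        except ValueError as exc:
            raise ValueError(f"row {i + 2}: {exc}") from exc  # +2: header + 1-based
        pmid = str(row["pmid"])
        if pmid in seen:
            raise ValueError(f"row {i + 2}: duplicate pmid {pmid!r}")
        seen.add(pmid)
        out.append(LabelledDocument(pmid=pmid, label=label))
    return out


def write_labels(labels: Iterable[LabelledDocument], path: Union[str, Path]) -> None:
    pd.DataFrame([{"pmid": l.pmid, "label": l.label} for l in labels]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Normalised corpus persistence (JSON lines, one record per line)

def write_corpus_jsonl(records: Iterable[DocumentRecord], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(asdict(rec), ensure_ascii=False) + "\n")


def read_corpus_jsonl(path: Union[str, Path]) -> list[DocumentRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                records.append(DocumentRecord(**json.loads(line)))
    return records


# ---------------------------------------------------------------------------
# Corpus statistics

def corpus_stats(
    records: list[DocumentRecord], labels: Iterable[LabelledDocument] | None = None
) -> pd.DataFrame:
    """Per-field availability and per-label prevalence, in percent.

    Availability of a field is 100 x (records with a non-empty value) /
    (total records); prevalence likewise over labels.
    """
    if not records:
        raise ValueError("corpus_stats requires a non-empty corpus")
    n = len(records)
    rows = []
    for name in FIELD_NAMES:
        present = sum(1 for r in records if getattr(r, name))
        rows.append({"field": name, "kind": "availability", "percent": 100.0 * present / n})
    if labels is not None:
        labels = list(labels)
        if labels:
            m = len(labels)
            for value in (RELEVANT, NOT_RELEVANT):
                count = sum(1 for l in labels if l.label == value)
                rows.append({"field": value, "kind": "prevalence", "percent": 100.0 * count / m})
    return pd.DataFrame(rows)
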