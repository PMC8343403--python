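"""Synthetic labelled corpora with the statistical structure of PK triage.

The generator emulates the features the classifier exploits in real
PubMed records: PK-parameter-like signal terms and numeric tokens that
occur far more often in abstracts of Relevant documents, a "Review"
publication type that marks Not Relevant records, a ~20% positive
prevalence, and ~13% of records with no abstract (which removes any
abstract-borne signal, as in real missing-abstract false negatives).
Background text is drawn from a Zipf-distributed synthetic vocabulary,
so vocabulary-frequency thresholds behave as they would on real text.

Everything is deterministic given the mandatory seed, and labels are
assigned by exact count rather than sampled, so stratified-split edge
cases are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from lxml import etree

from .corpus import DocumentRecord, LabelledDocument, RELEVANT, NOT_RELEVANT
from .preprocess import load_chemical_lexicon

#: PK-parameter-like signal terms; multi-word entries exercise n-grams.
DEFAULT_SIGNAL_TERMS = (
    "clearance",
    "half-life",
    "volume of distribution",
    "bioavailability",
    "AUC",
    "Cmax",
    "elimination rate constant",
)

_JOURNALS = (
    "J Pharmacokinet Pharmacodyn",
    "Clin Pharmacokinet",
    "Br J Clin Pharmacol",
    "Drug Metab Dispos",
    "Eur J Pharm Sci",
)

_MESH_POOL = (
    "Humans", "Animals", "Rats", "Male", "Female", "Adult",
    "Administration, Oral", "Injections, Intravenous", "Models, Biological",
    "Dose-Response Relationship, Drug", "Biological Availability",
)

_AFFILIATIONS = (
    "Department of Pharmacology, University A",
    "School of Pharmacy, University B",
    "Institute of Clinical Science, Hospital C",
)

_KEYWORD_POOL = ("pharmacokinetics", "population modelling", "drug monitoring", "toxicology")

_SPECIES = ("rats", "humans", "mice", "dogs", "healthy volunteers")


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    Defaults mirror the triage setting: 20% Relevant prevalence, 13%
    missing abstracts, strongly separable signal-term injection (0.9 in
    Relevant vs 0.05 in Not Relevant abstracts), and a weaker echo of
    the signal in titles.
    """

    n_docs: int
    seed: int
    prevalence: float = 0.2
    signal_terms: tuple[str, ...] = DEFAULT_SIGNAL_TERMS
    p_signal_relevant: float = 0.9
    p_signal_irrelevant: float = 0.05
    p_title_signal_relevant: float = 0.5
    p_title_signal_irrelevant: float = 0.02
    p_numeric_relevant: float = 0.8
    p_numeric_irrelevant: float = 0.3
    background_vocab_size: int = 500
    zipf_exponent: float = 1.1
    p_missing_abstract: float = 0.13
    p_review_not_relevant: float = 0.3
    abstract_length: tuple[int, int] = (30, 80)
    title_length: tuple[int, int] = (5, 10)

    def __post_init__(self) -> None:
        if self.n_docs < 10:
            raise ValueError("n_docs must be >= 10")
        for name in (
            "prevalence", "p_signal_relevant", "p_signal_irrelevant",
            "p_title_signal_relevant", "p_title_signal_irrelevant",
            "p_numeric_relevant", "p_numeric_irrelevant",
            "p_missing_abstract", "p_review_not_relevant",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def _zipf_words(rng: np.random.RandomState, vocab_size: int, exponent: float, n: int):
    ranks = np.arange(1, vocab_size + 1)
    probs = ranks ** (-exponent)
    probs /= probs.sum()
    idx = rng.choice(vocab_size, size=n, p=probs)
    return [f"term{i:03d}" for i in idx]


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[list[DocumentRecord], list[LabelledDocument]]:
    """Draw one labelled corpus under the configured conditions.

    The number of Relevant documents is exactly
    ``round(n_docs * prevalence)``; which documents are Relevant, and all
    their fields, depend only on the seed.
    """
    rng = np.random.RandomState(config.seed)
    n = config.n_docs
    n_rel = int(round(n * config.prevalence))
    labels01 = np.zeros(n, dtype=int)
    labels01[:n_rel] = 1
    rng.shuffle(labels01)

    lexicon = load_chemical_lexicon()
    records: list[DocumentRecord] = []
    labels: list[LabelledDocument] = []
    for i in range(n):
        relevant = bool(labels01[i])
        pmid = str(10_000_000 + i)

        # title: background words, sometimes prefixed with a PK-style
        # headline ("Pharmacokinetics of <term> in <species>") whose
        # shared carrier token survives document-frequency filtering
        t_lo, t_hi = config.title_length
        title_words = _zipf_words(
            rng, config.background_vocab_size, config.zipf_exponent,
            rng.randint(t_lo, t_hi + 1),
        )
        p_title = config.p_title_signal_relevant if relevant else config.p_title_signal_irrelevant
        if rng.rand() < p_title:
            term = config.signal_terms[rng.randint(len(config.signal_terms))]
            species = _SPECIES[rng.randint(len(_SPECIES))]
            title_words = ["Pharmacokinetics", "of", term, "in", species] + title_words[:3]
        title = " ".join(title_words)
        title = title[0].upper() + title[1:]

        # abstract: may be missing entirely; otherwise carries the signal
        abstract = ""
        if rng.rand() >= config.p_missing_abstract:
            a_lo, a_hi = config.abstract_length
            words = _zipf_words(
                rng, config.background_vocab_size, config.zipf_exponent,
                rng.randint(a_lo, a_hi + 1),
            )
            p_sig = config.p_signal_relevant if relevant else config.p_signal_irrelevant
            for term in config.signal_terms:
                if rng.rand() < p_sig:
                    words.insert(rng.randint(len(words) + 1), term)
            p_num = config.p_numeric_relevant if relevant else config.p_numeric_irrelevant
            if rng.rand() < p_num:
                for _ in range(rng.randint(1, 4)):
                    value = f"{rng.rand() * 100:.1f}"
                    words.insert(rng.randint(len(words) + 1), value)
            abstract = " ".join(words)

        if not relevant and rng.rand() < config.p_review_not_relevant:
            pub_types = ["Review"]
        else:
            pub_types = ["Journal Article"]

        mesh = list(
            rng.choice(_MESH_POOL, size=rng.randint(2, 6), replace=False)
        )
        if rng.rand() < (0.5 if relevant else 0.1):
            mesh.append("Pharmacokinetics")

        chemicals = list(
            rng.choice(lexicon, size=rng.randint(0, 3), replace=False)
        )
        authors = [
            f"Author{rng.randint(100):02d} Name{rng.randint(100):02d}"
            for _ in range(rng.randint(1, 4))
        ]
        keywords = (
            [str(k) for k in rng.choice(_KEYWORD_POOL, size=rng.randint(1, 3), replace=False)]
            if rng.rand() < 0.15
            else []
        )
        affiliations = (
            [_AFFILIATIONS[rng.randint(len(_AFFILIATIONS))]] if rng.rand() < 0.8 else []
        )

        records.append(
            DocumentRecord(
                pmid=pmid,
                title=title,
                abstract=abstract,
                authors=authors,
                journal=_JOURNALS[rng.randint(len(_JOURNALS))],
                publication_types=pub_types,
                keywords=keywords,
                mesh_terms=[str(m) for m in mesh],
                chemicals=[str(c) for c in chemicals],
                affiliations=affiliations,
            )
        )
        labels.append(
            LabelledDocument(pmid=pmid, label=RELEVANT if relevant else NOT_RELEVANT)
        )
    return records, labels


# ---------------------------------------------------------------------------
# Fixture XML emission

def emit_fixture_xml(records: Sequence[DocumentRecord]) -> bytes:
    """Serialise records as MEDLINE-dialect XML that round-trips exactly.

    Empty optional fields are omitted (an absent AbstractText re-parses
    to an empty abstract).
    """
    root = etree.Element("PubmedArticleSet")
    for rec in records:
        article_el = etree.SubElement(root, "PubmedArticle")
        cit = etree.SubElement(article_el, "MedlineCitation")
        etree.SubElement(cit, "PMID").text = rec.pmid
        art = etree.SubElement(cit, "Article")
        if rec.journal:
            j = etree.SubElement(art, "Journal")
            etree.SubElement(j, "Title").text = rec.journal
        etree.SubElement(art, "ArticleTitle").text = rec.title
        if rec.abstract:
            ab = etree.SubElement(art, "Abstract")
            etree.SubElement(ab, "AbstractText").text = rec.abstract
        if rec.authors:
            alist = etree.SubElement(art, "AuthorList")
            for name in rec.authors:
                a = etree.SubElement(alist, "Author")
                parts = name.rsplit(" ", 1)
                if len(parts) == 2:
                    etree.SubElement(a, "ForeName").text = parts[0]
                    etree.SubElement(a, "LastName").text = parts[1]
                else:
                    etree.SubElement(a, "LastName").text = name
        if rec.publication_types:
            pl = etree.SubElement(art, "PublicationTypeList")
            for pt in rec.publication_types:
                etree.SubElement(pl, "PublicationType").text = pt
        if rec.affiliations:
            for aff in rec.affiliations:
                ai = etree.SubElement(art, "AffiliationInfo")
                etree.SubElement(ai, "Affiliation").text = aff
        if rec.chemicals:
            cl = etree.SubElement(cit, "ChemicalList")
            for chem in rec.chemicals:
                c = etree.SubElement(cl, "Chemical")
                etree.SubElement(c, "NameOfSubstance").text = chem
        if rec.mesh_terms:
            ml = etree.SubElement(cit, "MeshHeadingList")
            for m in rec.mesh_terms:
                mh = etree.SubElement(ml, "MeshHeading")
                etree.SubElement(mh, "DescriptorName").text = m
        if rec.keywords:
            kl = etree.SubElement(cit, "KeywordList")
            for k in rec.keywords:
                etree.SubElement(kl, "Keyword").text = k
    return etree.tostring(
        root, xml_declaration=True, encoding="utf-8", pretty_print=True
    )
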