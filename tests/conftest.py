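import numpy as np
import pytest

from pktriage.corpus import DocumentRecord
from pktriage.simulate import GeneratorConfig, generate_corpus


FIXTURE_XML = b"""<?xml version="1.0" encoding="utf-8"?>
<PubmedArticleSet>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>11111</PMID>
      <Article>
        <Journal><Title>Clin Pharmacokinet</Title></Journal>
        <ArticleTitle>Pharmacokinetics of drug X in rats</ArticleTitle>
        <Abstract>
          <AbstractText Label="BACKGROUND">Clearance was 5.2 L/h.</AbstractText>
          <AbstractText Label="METHODS">Half-life was estimated in 12 rats.</AbstractText>
        </Abstract>
        <AuthorList>
          <Author><ForeName>Ada</ForeName><LastName>Smith</LastName></Author>
        </AuthorList>
        <PublicationTypeList>
          <PublicationType>Journal Article</PublicationType>
        </PublicationTypeList>
        <AffiliationInfo><Affiliation>University A</Affiliation></AffiliationInfo>
      </Article>
      <ChemicalList>
        <Chemical><NameOfSubstance>midazolam</NameOfSubstance></Chemical>
      </ChemicalList>
      <MeshHeadingList>
        <MeshHeading>
          <DescriptorName>Rats</DescriptorName>
          <QualifierName>metabolism</QualifierName>
        </MeshHeading>
      </MeshHeadingList>
      <KeywordList><Keyword>pharmacokinetics</Keyword></KeywordList>
    </MedlineCitation>
  </PubmedArticle>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>22222</PMID>
      <Article>
        <ArticleTitle>A review of something else</ArticleTitle>
        <PublicationTypeList>
          <PublicationType>Review</PublicationType>
        </PublicationTypeList>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>33333</PMID>
      <Article>
        <ArticleTitle>Unicode title with \xce\xbcg/mL units</ArticleTitle>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
</PubmedArticleSet>
"""


@pytest.fixture
def fixture_xml() -> bytes:
    return FIXTURE_XML


@pytest.fixture(scope="session")
def small_corpus():
    """120-document synthetic corpus with labels as (records, y01) arrays."""
    records, labels = generate_corpus(GeneratorConfig(n_docs=120, seed=11))
    y = np.array([1 if l.label == "Relevant" else 0 for l in labels])
    return records, y


@pytest.fixture(scope="session")
def medium_corpus():
    """600-document corpus under the default study conditions."""
    records, labels = generate_corpus(GeneratorConfig(n_docs=600, seed=5))
    y = np.array([1 if l.label == "Relevant" else 0 for l in labels])
    return records, y


def make_record(pmid="1", title="t", **kw) -> DocumentRecord:
    return DocumentRecord(pmid=pmid, title=title, **kw)
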