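import json

import numpy as np
import pytest

from atmbiblio import AuthorIndex, Corpus, Document, Vocabulary


def build_corpus(docs, n_words=None, n_authors=None, years=None, journals=None):
    """Corpus from [(token_ids, author_ids), ...] with synthetic labels."""
    if n_words is None:
        n_words = max(max(t) for t, _ in docs if t) + 1
    if n_authors is None:
        n_authors = max(max(a) for _, a in docs) + 1
    vocab = Vocabulary(f"w{i}" for i in range(n_words))
    authors = AuthorIndex(f"author {i}" for i in range(n_authors))
    documents = [
        Document(
            tokens=np.asarray(t, dtype=np.int32),
            authors=np.asarray(sorted(a), dtype=np.int32),
            year=years[i] if years else 2000 + i,
            journal=journals[i] if journals else "J",
        )
        for i, (t, a) in enumerate(docs)
    ]
    return Corpus(documents, vocab, authors)


@pytest.fixture
def tiny_corpus():
    """8 tokens, 2 topics' worth of structure, 2 authors."""
    return build_corpus(
        [([0, 1, 0], [0]), ([2, 3, 2], [1]), ([0, 2], [0, 1])], n_words=4
    )


@pytest.fixture
def jsonl_records_file(tmp_path):
    """3 JSONL records, one with an empty abstract."""
    rows = [
        {"record_id": "r1", "title": "t1",
         "abstract": "Tobacco smoking cessation treatment outcomes in tobacco smoking research",
         "authors": ["Smith JA", "Jones B"], "journal": "J Nic", "year": 2005,
         "mesh_terms": ["Smoking", "Humans"]},
        {"record_id": "r2", "title": "t2", "abstract": "",
         "authors": ["Lee C"], "journal": "J Nic", "year": 2006, "mesh_terms": []},
        {"record_id": "r3", "title": "t3",
         "abstract": "Nicotine dependence treatment and cessation outcomes in smoking populations",
         "authors": ["Jones B", "Lee C"], "journal": "J Tob", "year": 2007,
         "mesh_terms": ["Nicotine"]},
    ]
    path = tmp_path / "records.jsonl"
    path.write_text("\n".join(json.dumps(r) for r in rows) + "\n")
    return path


PUBMED_XML = """<?xml version="1.0"?>
<PubmedArticleSet>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>11111</PMID>
      <Article>
        <Journal>
          <JournalIssue><PubDate><Year>2004</Year></PubDate></JournalIssue>
          <Title>Nicotine &amp; Tobacco Research</Title>
        </Journal>
        <ArticleTitle>A study</ArticleTitle>
        <Abstract><AbstractText>Smokeless tobacco products and snus usage patterns.</AbstractText></Abstract>
        <AuthorList>
          <Author><LastName>Hatsukami</LastName><Initials>D</Initials></Author>
          <Author><LastName>Cummings</LastName><Initials>K</Initials></Author>
        </AuthorList>
      </Article>
      <MeshHeadingList>
        <MeshHeading><DescriptorName>Tobacco, Smokeless</DescriptorName></MeshHeading>
        <MeshHeading><DescriptorName>Humans</DescriptorName></MeshHeading>
        <MeshHeading><DescriptorName>Smoking</DescriptorName></MeshHeading>
        <MeshHeading><DescriptorName>Adult</DescriptorName></MeshHeading>
      </MeshHeadingList>
    </MedlineCitation>
  </PubmedArticle>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>22222</PMID>
      <Article>
        <Journal>
          <JournalIssue><PubDate><Year>2009</Year></PubDate></JournalIssue>
          <Title>Tobacco Control</Title>
        </Journal>
        <ArticleTitle>No abstract here</ArticleTitle>
        <AuthorList>
          <Author><LastName>Glantz</LastName><Initials>S</Initials></Author>
        </AuthorList>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
</PubmedArticleSet>
"""


@pytest.fixture
def pubmed_xml_file(tmp_path):
    path = tmp_path / "records.xml"
    path.write_text(PUBMED_XML)
    return path
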