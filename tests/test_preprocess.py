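"""Tokenisation, chemical masking, normalisation chain, Porter stemming."""

import pytest
from hypothesis import given, settings, strategies as st

from pktriage.porter import porter_stem
from pktriage.preprocess import (
    CHEM_MASK,
    DictionaryMasker,
    EntitySpanSet,
    TextPreprocessor,
    TokenSequence,
    detect_chemicals,
    load_stopwords,
    mask_entities,
    normalize_tokens,
    tokenize_field,
)

# Input/output pairs from the published definition of the algorithm
# (step examples carried through to the full algorithm's output).
PORTER_PAIRS = [
    ("caresses", "caress"), ("ponies", "poni"), ("ties", "ti"), ("caress", "caress"),
    ("cats", "cat"), ("feed", "feed"), ("agreed", "agre"), ("plastered", "plaster"),
    ("bled", "bled"), ("motoring", "motor"), ("sing", "sing"), ("conflated", "conflat"),
    ("troubled", "troubl"), ("sized", "size"), ("hopping", "hop"), ("tanned", "tan"),
    ("falling", "fall"), ("hissing", "hiss"), ("fizzed", "fizz"), ("failing", "fail"),
    ("filing", "file"), ("happy", "happi"), ("sky", "sky"),
    ("relational", "relat"), ("conditional", "condit"), ("rational", "ration"),
    ("valenci", "valenc"), ("hesitanci", "hesit"), ("digitizer", "digit"),
    ("conformabli", "conform"), ("radicalli", "radic"), ("differentli", "differ"),
    ("vileli", "vile"), ("analogousli", "analog"), ("vietnamization", "vietnam"),
    ("predication", "predic"), ("operator", "oper"), ("feudalism", "feudal"),
    ("decisiveness", "decis"), ("hopefulness", "hope"), ("callousness", "callous"),
    ("formaliti", "formal"), ("sensitiviti", "sensit"), ("sensibiliti", "sensibl"),
    ("triplicate", "triplic"), ("formative", "form"), ("formalize", "formal"),
    ("electriciti", "electr"), ("electrical", "electr"), ("hopeful", "hope"),
    ("goodness", "good"), ("revival", "reviv"), ("allowance", "allow"),
    ("inference", "infer"), ("airliner", "airlin"), ("gyroscopic", "gyroscop"),
    ("adjustable", "adjust"), ("defensible", "defens"), ("irritant", "irrit"),
    ("replacement", "replac"), ("adjustment", "adjust"), ("dependent", "depend"),
    ("adoption", "adopt"), ("communism", "commun"), ("activate", "activ"),
    ("angulariti", "angular"), ("homologous", "homolog"), ("effective", "effect"),
    ("bowdlerize", "bowdler"), ("probate", "probat"), ("rate", "rate"),
    ("cease", "ceas"), ("controll", "control"), ("roll", "roll"),
    # domain words
    ("clearance", "clearanc"), ("pharmacokinetics", "pharmacokinet"),
    ("estimated", "estim"), ("parameters", "paramet"),
]


@pytest.mark.parametrize("word,stem", PORTER_PAIRS)
def test_porter_reference_pairs(word, stem):
    assert porter_stem(word) == stem


class TestTokenize:
    def test_empty_text(self):
        assert tokenize_field("").tokens == ()

    def test_punctuation_boundaries_and_decimals(self):
        seq = tokenize_field("Clearance was 5.2 L/h.")
        assert list(seq.tokens) == ["Clearance", "was", "5.2", "L", "/", "h", "."]

    def test_hyphenated_terms_kept_whole(self):
        assert tokenize_field("half-life").tokens == ("half-life",)

    def test_all_nonspace_characters_recovered(self):
        text = "AUC(0-24) was 38.7 mg*h/L in n=12 subjects."
        tokens = tokenize_field(text).tokens
        assert "".join(tokens) == text.replace(" ", "")


class TestMaskEntities:
    def test_single_token_span(self):
        seq = TokenSequence("title", ("a", "midazolam", "b"))
        out = mask_entities(seq, EntitySpanSet(((1, 1),)))
        assert out.tokens == ("a", CHEM_MASK, "b")

    def test_empty_span_set_is_identity(self):
        seq = TokenSequence("title", ("a", "b"))
        assert mask_entities(seq, EntitySpanSet(())).tokens == seq.tokens

    def test_multitoken_span_collapses_to_one_mask(self):
        seq = TokenSequence("title", ("valproic", "acid", "levels"))
        out = mask_entities(seq, EntitySpanSet(((0, 1),)))
        assert out.tokens == (CHEM_MASK, "levels")
        assert len(out) == len(seq) - 1

    def test_overlapping_spans_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            EntitySpanSet(((0, 2), (1, 3)))

    def test_out_of_bounds_span_rejected(self):
        seq = TokenSequence("title", ("a",))
        with pytest.raises(ValueError, match="bounds"):
            mask_entities(seq, EntitySpanSet(((0, 5),)))


class TestNormalize:
    def test_all_digit_token_collapsed(self):
        seq = TokenSequence("title", ("123",))
        assert normalize_tokens(seq, set()).tokens == ("##",)

    def test_decimal_becomes_digit_mask(self):
        # digit test applies after internal-punctuation stripping: 3.5 -> 35 -> ##
        seq = TokenSequence("title", ("3.5",))
        assert normalize_tokens(seq, set()).tokens == ("##",)

    def test_stopword_dropped(self):
        seq = TokenSequence("title", ("the", "clearance"))
        assert normalize_tokens(seq).tokens == ("clearanc",)

    def test_punctuation_stripped_and_stemmed(self):
        seq = TokenSequence("title", ("Clearance,",))
        assert normalize_tokens(seq, set()).tokens == ("clearanc",)

    def test_token_reduced_to_nothing_dropped(self):
        seq = TokenSequence("title", ("...", "ok"))
        assert normalize_tokens(seq, set()).tokens == ("ok",)

    def test_mask_tokens_exempt(self):
        seq = TokenSequence("title", (CHEM_MASK, "##", "Dosing"))
        assert normalize_tokens(seq, set()).tokens == (CHEM_MASK, "##", "dose")

    @given(st.lists(st.text(alphabet="abcZ09.,-", min_size=1, max_size=8), max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_stages_without_stemming_idempotent(self, tokens):
        """lowercase/punct/digit/stopword stages are a projection."""
        tokens = [t for t in tokens if t]
        seq = TokenSequence("title", tuple(tokens))
        once = normalize_tokens(seq, load_stopwords(), stem=False)
        twice = normalize_tokens(once, load_stopwords(), stem=False)
        assert once.tokens == twice.tokens

    @given(st.lists(st.text(alphabet="abcDEF123.-", min_size=1, max_size=10), max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_output_has_no_uppercase_or_internal_punctuation(self, tokens):
        tokens = [t for t in tokens if t]
        out = normalize_tokens(TokenSequence("title", tuple(tokens)), set())
        for tok in out.tokens:
            if tok in (CHEM_MASK, "##"):
                continue
            assert tok == tok.lower()
            assert all(c.isalnum() or c == "_" for c in tok)


class TestDetectChemicals:
    def test_dictionary_hit(self):
        seq = TokenSequence("title", ("midazolam", "clearance"))
        spans = detect_chemicals(seq, DictionaryMasker(["midazolam"]))
        assert spans.spans == ((0, 0),)

    def test_empty_dictionary(self):
        seq = TokenSequence("title", ("midazolam",))
        assert detect_chemicals(seq, DictionaryMasker([])).spans == ()

    def test_multiword_entry_one_span(self):
        seq = TokenSequence("title", ("high", "valproic", "acid", "levels"))
        spans = detect_chemicals(seq, DictionaryMasker(["valproic acid"]))
        assert spans.spans == ((1, 2),)

    def test_case_insensitive(self):
        seq = TokenSequence("title", ("Midazolam",))
        spans = detect_chemicals(seq, DictionaryMasker(["midazolam"]))
        assert spans.spans == ((0, 0),)


def test_full_chain_masks_then_normalises():
    prep = TextPreprocessor(masker=DictionaryMasker(["midazolam"]))
    out = prep("Midazolam clearance was 5.2 L/h in the study.", "abstract")
    assert out[0] == CHEM_MASK
    assert "clearanc" in out and "##" in out
    assert "the" not in out and "was" not in out
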