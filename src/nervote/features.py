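"""Token-level features for biomedical named-entity extraction.

Fifteen feature families computed per token, designed to work without
external lexicons or domain resources: everything is derived from the
training corpus itself (word frequencies, head nouns, trigger verbs,
informative-word weights, content-word vocabulary) or from the token's
own orthography (shape, character class, capital/digit/hyphen patterns).

A :class:`FeatureTemplate` declares which families a base labeler uses
and with what window radii; varying templates is how heterogeneous base
classifiers are produced for the voting ensemble.
"""

from __future__ import annotations

import re
import warnings
import zlib
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .corpus import Corpus, Sentence
from .evaluation import extract_chunks

__all__ = [
    "FeatureTemplate",
    "FeatureResources",
    "ORTHOGRAPHIC_CATEGORIES",
    "STOPWORDS",
    "word_shape",
    "word_class",
    "orthographic_flags",
    "normalize_stem",
    "ne_weight",
    "build_informative_word_lists",
    "extract_content_word_vocab",
    "build_resources",
    "extract_features",
    "load_templates",
]

# Small general-English stopword list; the design goal is domain
# independence, so no external lexicon is shipped.
STOPWORDS = frozenset("""
a an and are as at be but by for from has have in is it its of on or that the
this to was were which will with we our can not no than then these those been
also both each between into through during after before above below under over
""".split())

_GREEK = frozenset("""
alpha beta gamma delta epsilon zeta eta theta iota kappa lambda mu nu xi
omicron pi rho sigma tau upsilon phi chi psi omega
""".split())


@dataclass(frozen=True)
class FeatureTemplate:
    """Declarative description of one base labeler's feature set.

    ``*_window`` are context radii in tokens (0 disables the column),
    ``ngram_order`` the maximum n for left-to-right context n-grams,
    ``affix_len`` the maximum prefix/suffix length of the current word,
    and ``dynamic_depth`` how many preceding output tags feed the
    dynamic feature.
    """

    name: str = "default"
    word_window: int = 2
    pos_window: int = 0
    chunk_window: int = 0
    ngram_order: int = 2
    affix_len: int = 3
    dynamic_depth: int = 0
    length: bool = True
    infrequent: bool = True
    normalization: bool = True
    word_class_flag: bool = True
    orthographic: bool = True
    head_noun: bool = True
    trigger: bool = True
    informative_words: bool = True
    content_words: bool = False
    unknown_token: bool = True

    def __post_init__(self) -> None:
        for win in (self.word_window, self.pos_window, self.chunk_window):
            if not 0 <= win <= 3:
                raise ValueError("context windows must be in [0, 3]")
        if self.ngram_order not in (1, 2):
            raise ValueError("ngram_order must be 1 or 2")
        if not 0 <= self.affix_len <= 4:
            raise ValueError("affix_len must be in [0, 4]")
        if not 0 <= self.dynamic_depth <= 3:
            raise ValueError("dynamic_depth must be in [0, 3]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "FeatureTemplate":
        return cls(**dict(d))


def load_templates(path: str | Path) -> list[FeatureTemplate]:
    """Load named feature templates from a YAML mapping file."""
    import yaml

    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    templates = []
    for name, body in data.items():
        body = dict(body or {})
        body.setdefault("name", name)
        templates.append(FeatureTemplate.from_dict(body))
    return templates


# ---------------------------------------------------------------- shapes

def word_shape(surface: str) -> str:
    """Map capitals to 'A', lowercase to 'a', digit runs to a single '0'.

    'IL' -> 'AA', 'IL-2' -> 'AA-0', 'IL-88' -> 'AA-0'.
    """
    if not surface:
        raise ValueError("empty surface")
    out: list[str] = []
    in_digits = False
    for ch in surface:
        if ch.isdigit():
            if not in_digits:
                out.append("0")
            in_digits = True
            continue
        in_digits = False
        if ch.isupper():
            out.append("A")
        elif ch.islower():
            out.append("a")
        else:
            out.append(ch)
    return "".join(out)


def word_class(surface: str) -> str:
    """Coarser shape: A/a/O/- per character class, runs squeezed to one.

    Capitals -> 'A', lowercase -> 'a', digits -> 'O', everything else
    -> '-'; consecutive identical class characters collapse, so
    'IL23R' -> 'AOA' and 'mRNA' -> 'aA'.
    """
    if not surface:
        raise ValueError("empty surface")
    out: list[str] = []
    for ch in surface:
        if ch.isupper():
            c = "A"
        elif ch.islower():
            c = "a"
        elif ch.isdigit():
            c = "O"
        else:
            c = "-"
        if not out or out[-1] != c:
            out.append(c)
    return "".join(out)


def normalize_stem(word: str) -> str:
    """Crude stem: lower-case, strip common inflections, collapse digits.

    Approximate by design; it exists to merge plural/inflected variants,
    not to be a linguistic stemmer.
    """
    w = word.lower()
    for suf in ("ing", "ed", "es", "s"):
        if len(w) > len(suf) + 2 and w.endswith(suf):
            w = w[: -len(suf)]
            break
    return re.sub(r"\d+", "0", w)


ORTHOGRAPHIC_CATEGORIES: tuple[str, ...] = (
    "InitCap", "AllCaps", "InCap", "CapMixAlpha", "DigitOnly",
    "DigitSpecial", "DigitAlpha", "AlphaDigitAlpha", "Hyphen",
    "CapLowAlpha", "CapsAndDigits", "RomanNumeral", "StopWord",
    "ATGCSeq", "AlphaDigit", "DigitCommaDigit", "GreekLetter",
    "LowMixAlpha",
)


def orthographic_flags(surface: str) -> dict[str, int]:
    """Binary capitalization/digit/special-character indicators.

    Categories are not mutually exclusive; e.g. 'IL23R' fires InitCap,
    AlphaDigitAlpha and CapsAndDigits at once.
    """
    s = surface
    letters = [c for c in s if c.isalpha()]
    has_upper = any(c.isupper() for c in s)
    has_lower = any(c.islower() for c in s)
    has_digit = any(c.isdigit() for c in s)
    flags = {
        "InitCap": int(s[0].isupper()),
        "AllCaps": int(bool(letters) and all(c.isupper() for c in letters)
                       and not has_digit and len(s) > 1 and s.isalpha()),
        "InCap": int(any(c.isupper() for c in s[1:]) and not s[0].isupper()),
        "CapMixAlpha": int(s.isalpha() and s[0].isupper() and has_lower
                           and any(c.isupper() for c in s[1:])),
        "DigitOnly": int(s.isdigit()),
        "DigitSpecial": int(has_digit and not letters and not s.isdigit()),
        "DigitAlpha": int(bool(re.fullmatch(r"\d+[A-Za-z].*", s))),
        "AlphaDigitAlpha": int(bool(re.fullmatch(r"[A-Za-z]+\d+[A-Za-z]+", s))),
        "Hyphen": int("-" in s),
        "CapLowAlpha": int(bool(re.fullmatch(r"[A-Z][a-z]+", s))),
        "CapsAndDigits": int(has_digit and has_upper),
        "RomanNumeral": int(bool(re.fullmatch(r"[IVXLCDM]+", s))),
        "StopWord": int(s.lower() in STOPWORDS),
        "ATGCSeq": int(len(s) >= 2 and bool(re.fullmatch(r"[ATGC]+", s))),
        "AlphaDigit": int(bool(re.fullmatch(r"[A-Za-z]+\d+", s))),
        "DigitCommaDigit": int(bool(re.fullmatch(r"\d+,\d+", s))),
        "GreekLetter": int(s.lower() in _GREEK),
        "LowMixAlpha": int(s.isalpha() and s[0].islower() and has_upper),
    }
    return flags


# ------------------------------------------------------- corpus resources

def ne_weight(word: str, inside_count: int, total_count: int) -> float:
    """Share of a word's training occurrences that fall inside NE spans.

    Ranges over [0, 1]; 1 means the word appears only inside entity
    mentions, 0 never.  Basis of the five informative-word classes.
    """
    if total_count <= 0:
        raise ValueError("total_count must be positive")
    if not 0 <= inside_count <= total_count:
        raise ValueError("need 0 <= inside_count <= total_count")
    return inside_count / total_count


_NONWORD_RE = re.compile(r"^[\W\d_]+$")

# Equal-width NEweight bins over (0, 1]; bin i holds (edges[i], edges[i+1]].
INFORMATIVE_BIN_EDGES = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


def build_informative_word_lists(
    corpus: Corpus,
    min_inside: int = 2,
    bin_edges: Sequence[float] = INFORMATIVE_BIN_EDGES,
) -> tuple[tuple[frozenset[str], ...], dict[str, float]]:
    """Five informative-word sets binned by NEweight, plus the weights.

    Candidates are words occurring inside multiword entity mentions,
    excluding digit/number/symbol tokens; words with fewer than
    ``min_inside`` in-entity occurrences are dropped; survivors are
    binned into five equal-width NEweight classes.
    """
    inside: Counter[str] = Counter()
    total: Counter[str] = Counter()
    candidates: set[str] = set()
    for sent in corpus:
        surfaces = sent.surfaces
        total.update(surfaces)
        for ch in extract_chunks(sent.labels):
            span = surfaces[ch.start: ch.end + 1]
            for w in span:
                inside[w] += 1
            if len(span) > 1:
                candidates.update(w for w in span if not _NONWORD_RE.match(w))
    weights: dict[str, float] = {}
    bins: list[set[str]] = [set() for _ in range(len(bin_edges) - 1)]
    for w in candidates:
        if inside[w] < min_inside:
            continue
        nw = ne_weight(w, inside[w], total[w])
        weights[w] = nw
        for i in range(len(bins)):
            if bin_edges[i] < nw <= bin_edges[i + 1]:
                bins[i].add(w)
                break
    return tuple(frozenset(b) for b in bins), weights


_CONTENT_DROP_RE = re.compile(r"^[\W\d_]+$")


def extract_content_word_vocab(
    corpus: Corpus, window: int = 3, size: int = 10
) -> list[str]:
    """The ``size`` most frequent content words near entity tokens.

    Counts lower-cased unigrams within ``window`` positions of every
    entity-labeled token over the linearized training corpus (crossing
    sentence boundaries); stopwords, numbers and symbols are removed.
    Ties break lexicographically.
    """
    flat_words: list[str] = []
    entity_pos: list[int] = []
    for sent in corpus:
        for tok in sent:
            if tok.label != "O":
                entity_pos.append(len(flat_words))
            flat_words.append(tok.surface)
    if not entity_pos:
        warnings.warn("corpus has no entity mentions; content vocabulary "
                      "is empty", stacklevel=2)
        return []
    counts: Counter[str] = Counter()
    for p in entity_pos:
        lo, hi = max(0, p - window), min(len(flat_words), p + window + 1)
        for q in range(lo, hi):
            w = flat_words[q].lower()
            if w in STOPWORDS or _CONTENT_DROP_RE.match(w):
                continue
            counts[w] += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    vocab = [w for w, _ in ranked[:size]]
    if len(vocab) < size:
        warnings.warn(
            f"only {len(vocab)} content words survive filtering", stacklevel=2
        )
    return vocab


@dataclass(frozen=True)
class FeatureResources:
    """Training-corpus-derived tables consumed by feature extraction."""

    word_counts: Mapping[str, int] = field(default_factory=dict)
    informative_lists: tuple[frozenset[str], ...] = tuple(
        frozenset() for _ in range(5)
    )
    informative_weights: Mapping[str, float] = field(default_factory=dict)
    head_noun_unigrams: frozenset[str] = frozenset()
    head_noun_bigrams: frozenset[tuple[str, str]] = frozenset()
    trigger_verbs: frozenset[str] = frozenset()
    content_vocab: tuple[str, ...] = ()
    content_window: int = 3
    seen_vocab: frozenset[str] = frozenset()
    length_threshold: int = 5
    infrequent_threshold: int = 10
    unknown_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.informative_lists) != 5:
            raise ValueError("exactly five informative-word lists required")


def build_resources(
    corpus: Corpus,
    min_head_freq: int = 2,
    min_trigger_freq: int = 2,
    content_window: int = 3,
    length_threshold: int = 5,
    infrequent_threshold: int = 10,
    unknown_seed: int = 0,
) -> FeatureResources:
    """Derive all feature resources from a labeled training corpus.

    Head nouns are the final one/two tokens of entity mentions, trigger
    verbs the words immediately preceding mentions, both kept only above
    a minimum training frequency.
    """
    word_counts: Counter[str] = Counter()
    head_uni: Counter[str] = Counter()
    head_bi: Counter[tuple[str, str]] = Counter()
    trig: Counter[str] = Counter()
    for sent in corpus:
        surfaces = sent.surfaces
        word_counts.update(surfaces)
        for ch in extract_chunks(sent.labels):
            head_uni[surfaces[ch.end]] += 1
            if ch.end > ch.start:
                head_bi[(surfaces[ch.end - 1], surfaces[ch.end])] += 1
            if ch.start > 0:
                trig[surfaces[ch.start - 1]] += 1
    informative_lists, weights = build_informative_word_lists(corpus)
    has_entities = any(
        lab != "O" for s in corpus for lab in s.labels
    )
    content_vocab = (
        tuple(extract_content_word_vocab(corpus, window=content_window))
        if has_entities else ()
    )
    return FeatureResources(
        word_counts=dict(word_counts),
        informative_lists=informative_lists,
        informative_weights=weights,
        head_noun_unigrams=frozenset(
            w for w, c in head_uni.items() if c >= min_head_freq
        ),
        head_noun_bigrams=frozenset(
            b for b, c in head_bi.items() if c >= min_trigger_freq
        ),
        trigger_verbs=frozenset(
            w for w, c in trig.items() if c >= min_trigger_freq
        ),
        content_vocab=content_vocab,
        content_window=content_window,
        seen_vocab=frozenset(word_counts),
        length_threshold=length_threshold,
        infrequent_threshold=infrequent_threshold,
        unknown_seed=unknown_seed,
    )


# ---------------------------------------------------------- extraction

def _ctx(values: Sequence[str | None], pos: int, off: int) -> str:
    i = pos + off
    if i < 0:
        return "<s>"
    if i >= len(values):
        return "</s>"
    v = values[i]
    return v if v is not None else "<none>"


def extract_features(
    sentence: Sentence,
    position: int,
    template: FeatureTemplate,
    resources: FeatureResources,
    previous_tags: Sequence[str] = (),
    training: bool = False,
) -> dict[str, object]:
    """Feature dict for one token; only gold-free, causal information.

    ``previous_tags`` are the already-assigned labels of the tokens
    before ``position`` (gold during training, predictions during greedy
    decoding); nothing from the current or future tokens' labels is ever
    inspected, so decoding-time extraction is valid.

    During training the unknown-token bit is randomized (every word is
    "seen", so the bit would be constant); the bit is a deterministic
    hash of (seed, position, surface) so a fixed run seed gives
    reproducible features regardless of extraction order.
    """
    if not 0 <= position < len(sentence):
        raise IndexError("token position out of range")
    toks = sentence.tokens
    word = toks[position].surface
    surfaces = [t.surface for t in toks]
    feats: dict[str, object] = {"w[0]": word}

    w = template.word_window
    ctx = {d: _ctx(surfaces, position, d) for d in range(-w, w + 1)}
    for d in range(-w, w + 1):
        if d != 0:
            feats[f"w[{d}]"] = ctx[d]
    if template.ngram_order >= 2:
        for d in range(-w, w):
            feats[f"w[{d}]|w[{d + 1}]"] = f"{ctx[d]}|{ctx[d + 1]}"

    if template.pos_window > 0:
        poss = [t.pos for t in toks]
        for d in range(-template.pos_window, template.pos_window + 1):
            feats[f"pos[{d}]"] = _ctx(poss, position, d)
    if template.chunk_window > 0:
        chunks = [t.chunk for t in toks]
        for d in range(-template.chunk_window, template.chunk_window + 1):
            feats[f"chk[{d}]"] = _ctx(chunks, position, d)

    for k in range(1, min(template.affix_len, len(word)) + 1):
        feats[f"pre{k}"] = word[:k]
        feats[f"suf{k}"] = word[-k:]

    if template.length:
        feats["long"] = int(len(word) > resources.length_threshold)
    if template.infrequent:
        feats["infrequent"] = int(
            resources.word_counts.get(word, 0) < resources.infrequent_threshold
        )
    if template.normalization:
        feats["shape"] = word_shape(word)
        feats["stem"] = normalize_stem(word)
    if template.word_class_flag:
        feats["wc"] = word_class(word)
    if template.orthographic:
        for cat, v in orthographic_flags(word).items():
            feats[f"ortho:{cat}"] = v
    if template.head_noun:
        hit = word in resources.head_noun_unigrams
        if not hit and position > 0:
            hit = (surfaces[position - 1], word) in resources.head_noun_bigrams
        if not hit and position + 1 < len(surfaces):
            hit = (word, surfaces[position + 1]) in resources.head_noun_bigrams
        feats["head_noun"] = int(hit)
    if template.trigger:
        feats["trigger"] = int(word in resources.trigger_verbs)
    if template.informative_words:
        for i, lst in enumerate(resources.informative_lists, start=1):
            feats[f"inf{i}"] = int(word in lst)
    if template.content_words:
        if not resources.content_vocab:
            raise ValueError(
                "content_words feature enabled but the resource vocabulary "
                "is empty; build resources on a labeled corpus first"
            )
        win = resources.content_window
        lo, hi = max(0, position - win), min(len(surfaces), position + win + 1)
        nearby = {surfaces[q].lower() for q in range(lo, hi)}
        for t in resources.content_vocab:
            feats[f"cw:{t}"] = int(t in nearby)
    if template.unknown_token:
        if training:
            h = zlib.crc32(
                f"{resources.unknown_seed}:{position}:{word}".encode()
            )
            feats["unknown"] = h & 1
        else:
            feats["unknown"] = int(word not in resources.seen_vocab)
    for depth in range(1, template.dynamic_depth + 1):
        tags = [
            previous_tags[position - d] if 0 <= position - d < len(previous_tags)
            else "<s>"
            for d in range(depth, 0, -1)
        ]
        feats[f"dyn{depth}"] = "|".join(tags)
    return feats
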