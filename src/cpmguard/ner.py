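"""Lexicon-driven segmentation, BIO tagging, and span-level NER evaluation.

The front end of the monitoring pipeline: free-text course records and
discharge summaries are segmented with a unigram maximum-probability model
over a professional dictionary, tagged with a sequence model into three
entity categories — DIS (disease), SYM (symptom), ZCY (Chinese patent
medicine) — and the recognised spans are linked to knowledge-graph nodes
by exact name, alias, or fuzzy match.

Token granularity: ideographic text is split into characters, anything
else into whitespace tokens, so the same code paths serve Chinese clinical
text and the whitespace pseudo-language used by the synthetic fixtures.

The default tagger backend is an averaged structured perceptron — a
first-order conditional sequence model over per-token features decoded by
Viterbi best-path search.  The backend registry accepts plugins so a
heavier contextual encoder can be substituted without touching the rest
of the pipeline.
"""

from __future__ import annotations

import difflib
import json
import random
import unicodedata
from collections import defaultdict
from dataclasses import dataclass, field
from fractions import Fraction

LABELS = ("DIS", "SYM", "ZCY")
LABEL_TO_ETYPE = {"DIS": "disease", "SYM": "symptom", "ZCY": "cpm_drug"}

#: pseudo-frequency for a single out-of-vocabulary token, against the same
#: lexicon total; below 1 so any in-lexicon word is preferred.
OOV_FREQ = Fraction(1, 2)


class NerError(ValueError):
    pass


# ---------------------------------------------------------------- tokenizing


def _is_ideographic(ch: str) -> bool:
    return unicodedata.category(ch) == "Lo" and ord(ch) > 0x2E7F


def tokenize(text: str) -> list[str]:
    """Characters for ideographic scripts, whitespace tokens otherwise."""
    if any(_is_ideographic(ch) for ch in text):
        return [ch for ch in text if not ch.isspace()]
    return text.split()


def _joiner(tokens: list[str]) -> str:
    # character-mode text glues without spaces; token-mode with spaces
    return "" if tokens and all(len(t) == 1 and _is_ideographic(t[0]) for t in tokens) else " "


# ------------------------------------------------------------------- lexicon


@dataclass
class Lexicon:
    """Professional dictionary: word -> (frequency, category).

    Words may be multi-token phrases; internally each entry stores its
    token split so the segmenter can match spans.
    """

    entries: dict[str, tuple[int, str]] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(freq for freq, _ in self.entries.values())

    @property
    def max_word_tokens(self) -> int:
        return max((len(tokenize(w)) for w in self.entries), default=1)

    def frequency(self, word: str) -> int | None:
        entry = self.entries.get(word)
        return entry[0] if entry else None

    def category(self, word: str) -> str | None:
        entry = self.entries.get(word)
        return entry[1] if entry else None


def build_lexicon(entries) -> Lexicon:
    """Build a lexicon from (word, frequency, category) triples.

    Duplicate words have their frequencies summed; the first non-general
    category seen for a word wins on conflict.
    """
    items = list(entries)
    if not items:
        raise NerError("lexicon entries must be non-empty")
    lex = Lexicon()
    for word, freq, category in items:
        if freq <= 0 or int(freq) != freq:
            raise NerError(f"word {word!r}: frequency must be a positive integer")
        if category not in (*LABELS, "general"):
            raise NerError(f"word {word!r}: unknown category {category!r}")
        if word in lex.entries:
            old_freq, old_cat = lex.entries[word]
            kept = old_cat if old_cat != "general" else category
            lex.entries[word] = (old_freq + int(freq), kept)
        else:
            lex.entries[word] = (int(freq), category)
    return lex


def save_lexicon(lex: Lexicon, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for word in sorted(lex.entries):
            freq, cat = lex.entries[word]
            fh.write(f"{word}\t{freq}\t{cat}\n")


def load_lexicon(path) -> Lexicon:
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise NerError(f"lexicon line {lineno}: expected 3 tab-separated fields")
            rows.append((parts[0], int(parts[1]), parts[2]))
    return build_lexicon(rows)


# -------------------------------------------------------------- segmentation


def segmentation_score(words: list[str], lexicon: Lexicon) -> Fraction:
    """Exact product of per-word probabilities (OOV single tokens smoothed).

    Maximising this product is equivalent to maximising the sum of log
    unigram probabilities; Fractions keep ties exact.
    """
    total = Fraction(lexicon.total)
    prob = Fraction(1)
    for w in words:
        freq = lexicon.frequency(w)
        if freq is None:
            if len(tokenize(w)) != 1:
                raise NerError(f"multi-token word {w!r} not in lexicon")
            prob *= OOV_FREQ / total
        else:
            prob *= Fraction(freq) / total
    return prob


def _better(cand: tuple, best: tuple | None) -> bool:
    """Candidate ordering: higher probability, then fewer words, then
    lexicographically smaller word tuple."""
    if best is None:
        return True
    cp, cn, cw = cand
    bp, bn, bw = best
    if cp != bp:
        return cp > bp
    if cn != bn:
        return cn < bn
    return cw < bw


def segment(text, lexicon: Lexicon) -> list[str]:
    """Maximum-probability segmentation by dynamic programming.

    ``text`` may be a raw string (tokenised internally) or a pre-split
    token list.  Every lexicon word spanning consecutive tokens is a
    candidate; any single token is usable out-of-vocabulary with a smoothed
    pseudo-frequency.  The concatenation of the output always equals the
    input token sequence.
    """
    if not lexicon.entries:
        raise NerError("cannot segment with an empty lexicon")
    tokens = tokenize(text) if isinstance(text, str) else list(text)
    n = len(tokens)
    if n == 0:
        return []
    joiner = _joiner(tokens)
    total = Fraction(lexicon.total)
    max_span = max(lexicon.max_word_tokens, 1)

    # best[i]: (prob, n_words, words_tuple) over tokens[:i]
    best: list[tuple | None] = [None] * (n + 1)
    best[0] = (Fraction(1), 0, ())
    for i in range(n):
        if best[i] is None:
            continue
        prob_i, nw_i, words_i = best[i]
        hi = min(n, i + max_span)
        for j in range(i + 1, hi + 1):
            word = joiner.join(tokens[i:j])
            freq = lexicon.frequency(word)
            if freq is None:
                if j - i != 1:
                    continue
                wprob = OOV_FREQ / total
            else:
                wprob = Fraction(freq) / total
            cand = (prob_i * wprob, nw_i + 1, words_i + (word,))
            if _better(cand, best[j]):
                best[j] = cand
    assert best[n] is not None  # single-token OOV fallback guarantees a path
    return list(best[n][2])


def segment_positions(text, lexicon: Lexicon) -> list[tuple[str, int, int]]:
    """Like :func:`segment` but with (word, start_token, end_token) spans."""
    tokens = tokenize(text) if isinstance(text, str) else list(text)
    words = segment(tokens, lexicon) if tokens else []
    out = []
    pos = 0
    for w in words:
        width = len(tokenize(w)) if _joiner(tokens) == " " else len(w)
        out.append((w, pos, pos + width))
        pos += width
    return out


# ------------------------------------------------------------------ BIO tags


@dataclass(frozen=True)
class EntityMention:
    start: int
    end: int  # half-open token offsets
    label: str
    surface: str = ""
    entity_id: str | None = None
    link_method: str = "unlinked"

    def __post_init__(self):
        if self.label not in LABELS:
            raise NerError(f"unknown mention label {self.label!r}")
        if not (0 <= self.start < self.end):
            raise NerError(f"bad mention span [{self.start}, {self.end})")


def _check_disjoint(mentions) -> list[EntityMention]:
    ms = sorted(mentions, key=lambda m: (m.start, m.end))
    for prev, cur in zip(ms, ms[1:]):
        if cur.start < prev.end:
            raise NerError(
                f"overlapping mentions [{prev.start},{prev.end}) and "
                f"[{cur.start},{cur.end})"
            )
    return ms


def bio_encode(n_tokens: int, mentions) -> list[str]:
    """Render mentions as a BIO tag sequence (B-X opens, I-X continues)."""
    ms = _check_disjoint(mentions)
    if ms and ms[-1].end > n_tokens:
        raise NerError("mention extends beyond the token sequence")
    tags = ["O"] * n_tokens
    for m in ms:
        tags[m.start] = f"B-{m.label}"
        for i in range(m.start + 1, m.end):
            tags[i] = f"I-{m.label}"
    return tags


def bio_decode(tokens: list[str], tags: list[str]) -> list[EntityMention]:
    """Decode BIO tags to mentions; a dangling I-X is repaired to B-X."""
    if len(tokens) != len(tags):
        raise NerError("tokens and tags must have equal length")
    for t in tags:
        if t != "O" and not (
            len(t) > 2 and t[1] == "-" and t[0] in "BI" and t[2:] in LABELS
        ):
            raise NerError(f"unknown BIO tag {t!r}")
    joiner = _joiner(tokens)
    mentions = []
    start = None
    label = None
    for i, tag in enumerate(tags):
        if tag == "O":
            if start is not None:
                mentions.append((start, i, label))
                start = None
            continue
        prefix, x = tag[0], tag[2:]
        if prefix == "B" or (start is None) or (x != label):
            # fresh B, or dangling/label-switching I repaired to B
            if start is not None:
                mentions.append((start, i, label))
            start, label = i, x
    if start is not None:
        mentions.append((start, len(tags), label))
    return [
        EntityMention(s, e, lab, surface=joiner.join(tokens[s:e]))
        for s, e, lab in mentions
    ]


# ----------------------------------------------------------------- sequences


@dataclass
class BIOSequence:
    tokens: list[str]
    tags: list[str]

    def __post_init__(self):
        if len(self.tokens) != len(self.tags):
            raise NerError("BIOSequence: tokens and tags must align")


def save_corpus(corpus: list[BIOSequence], path) -> None:
    """CoNLL-style two-column file: token TAB tag, blank line between sequences."""
    with open(path, "w", encoding="utf-8") as fh:
        for seq in corpus:
            for tok, tag in zip(seq.tokens, seq.tags):
                fh.write(f"{tok}\t{tag}\n")
            fh.write("\n")


def load_corpus(path) -> list[BIOSequence]:
    corpus: list[BIOSequence] = []
    tokens: list[str] = []
    tags: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                if tokens:
                    corpus.append(BIOSequence(tokens, tags))
                    tokens, tags = [], []
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise NerError(f"corpus line {lineno}: expected 'token<TAB>tag'")
            tokens.append(parts[0])
            tags.append(parts[1])
    if tokens:
        corpus.append(BIOSequence(tokens, tags))
    return corpus


# -------------------------------------------------------------------- tagger

TAG_VOCAB = ("O",) + tuple(f"{p}-{x}" for x in LABELS for p in "BI")


def _token_features(tokens: list[str], lexicon: Lexicon | None) -> list[list[str]]:
    """Per-token emission features: identity, neighbours, lexicon category,
    and position-in-word from the maximum-probability segmentation."""
    n = len(tokens)
    seg_pos = ["S"] * n
    seg_cat = ["none"] * n
    if lexicon is not None and lexicon.entries and n:
        for word, s, e in segment_positions(tokens, lexicon):
            cat = lexicon.category(word) or "oov"
            for i in range(s, e):
                seg_pos[i] = "B" if i == s else "I"
                seg_cat[i] = cat
    feats = []
    for i, tok in enumerate(tokens):
        f = [
            "bias",
            f"tok={tok}",
            f"prev={tokens[i - 1] if i else '<s>'}",
            f"next={tokens[i + 1] if i + 1 < n else '</s>'}",
            f"segpos={seg_pos[i]}",
            f"segcat={seg_cat[i]}",
            f"segcat+pos={seg_cat[i]}|{seg_pos[i]}",
        ]
        feats.append(f)
    return feats


def _bio_transition_allowed(prev: str, cur: str) -> bool:
    # hard BIO constraint: I-X only continues a B-X / I-X run
    if cur == "O" or cur.startswith("B-"):
        return True
    x = cur[2:]
    return prev in (f"B-{x}", f"I-{x}")


def _viterbi(
    feats: list[list[str]],
    weights: dict[str, dict[str, float]],
    trans: dict[tuple[str, str], float],
) -> list[str]:
    n = len(feats)
    if n == 0:
        return []
    tags = TAG_VOCAB
    emit = []
    for f in feats:
        scores = {}
        for tag in tags:
            w = weights.get(tag)
            scores[tag] = sum(w.get(feat, 0.0) for feat in f) if w else 0.0
        emit.append(scores)
    # delta[tag] = (score, path); deterministic tie-break by tag vocab order
    delta = {
        tag: (emit[0][tag] + trans.get(("<s>", tag), 0.0), [tag])
        for tag in tags
        if _bio_transition_allowed("<s>", tag)
    }
    for i in range(1, n):
        new = {}
        for tag in tags:
            best_score, best_path = None, None
            for prev in delta:
                if not _bio_transition_allowed(prev, tag):
                    continue
                s = delta[prev][0] + trans.get((prev, tag), 0.0) + emit[i][tag]
                if best_score is None or s > best_score:
                    best_score, best_path = s, delta[prev][1]
            if best_score is not None:
                new[tag] = (best_score, best_path + [tag])
        delta = new
    best_tag = max(delta, key=lambda t: (delta[t][0], -TAG_VOCAB.index(t)))
    return delta[best_tag][1]


@dataclass
class TaggerModel:
    """A trained sequence tagger: backend id, parameters, label vocab, seed.

    Tagging is fully deterministic given the stored parameters.
    """

    backend: str
    weights: dict  # tag -> {feature -> weight}
    transitions: dict  # "prev>tag" -> weight (string keys for JSON)
    seed: int
    labels: tuple[str, ...] = LABELS

    def _trans(self) -> dict[tuple[str, str], float]:
        return {tuple(k.split(">", 1)): v for k, v in self.transitions.items()}

    def predict_tags(self, tokens: list[str], lexicon: Lexicon | None) -> list[str]:
        feats = _token_features(tokens, lexicon)
        return _viterbi(feats, self.weights, self._trans())

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "backend": self.backend,
                    "seed": self.seed,
                    "labels": list(self.labels),
                    "weights": self.weights,
                    "transitions": self.transitions,
                },
                fh,
                ensure_ascii=False,
                sort_keys=True,
            )

    @classmethod
    def load(cls, path) -> "TaggerModel":
        with open(path, "r", encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            backend=d["backend"],
            weights=d["weights"],
            transitions=d["transitions"],
            seed=d["seed"],
            labels=tuple(d["labels"]),
        )


BACKENDS: dict[str, object] = {}


def register_backend(name: str, trainer) -> None:
    """Plug in an alternative trainer: corpus, lexicon, seed -> TaggerModel."""
    BACKENDS[name] = trainer


def _train_perceptron(
    corpus: list[BIOSequence],
    lexicon: Lexicon | None,
    seed: int,
    epochs: int = 8,
) -> TaggerModel:
    """Averaged structured perceptron with Viterbi decoding."""
    rng = random.Random(seed)
    weights: dict[str, dict[str, float]] = {t: defaultdict(float) for t in TAG_VOCAB}
    trans: dict[tuple[str, str], float] = defaultdict(float)
    acc_w: dict[str, dict[str, float]] = {t: defaultdict(float) for t in TAG_VOCAB}
    acc_t: dict[tuple[str, str], float] = defaultdict(float)
    featcache = [_token_features(seq.tokens, lexicon) for seq in corpus]
    order = list(range(len(corpus)))
    step = 0
    n_steps = epochs * len(corpus)
    for _ in range(epochs):
        rng.shuffle(order)
        for idx in order:
            step += 1
            seq, feats = corpus[idx], featcache[idx]
            pred = _viterbi(feats, weights, trans)
            remain = n_steps - step + 1  # weight future steps for averaging
            prev_g, prev_p = "<s>", "<s>"
            for i, (gold, hyp) in enumerate(zip(seq.tags, pred)):
                if gold != hyp:
                    for f in feats[i]:
                        weights[gold][f] += 1.0
                        weights[hyp][f] -= 1.0
                        acc_w[gold][f] += remain
                        acc_w[hyp][f] -= remain
                if (prev_g, gold) != (prev_p, hyp):
                    trans[(prev_g, gold)] += 1.0
                    trans[(prev_p, hyp)] -= 1.0
                    acc_t[(prev_g, gold)] += remain
                    acc_t[(prev_p, hyp)] -= remain
                prev_g, prev_p = gold, hyp
    denom = float(max(n_steps, 1))
    final_w = {
        t: {f: v / denom for f, v in acc_w[t].items() if v != 0.0} for t in TAG_VOCAB
    }
    final_t = {f"{a}>{b}": v / denom for (a, b), v in acc_t.items() if v != 0.0}
    return TaggerModel(
        backend="default_statistical", weights=final_w, transitions=final_t, seed=seed
    )


register_backend("default_statistical", _train_perceptron)


def train_tagger(
    corpus: list[BIOSequence],
    backend: str = "default_statistical",
    seed: int = 0,
    lexicon: Lexicon | None = None,
    **backend_kwargs,
) -> TaggerModel:
    if not corpus:
        raise NerError("training corpus is empty")
    trainer = BACKENDS.get(backend)
    if trainer is None:
        raise NerError(f"unknown tagger backend {backend!r}")
    return trainer(corpus, lexicon, seed, **backend_kwargs)


def tag_text(
    model: TaggerModel, text, lexicon: Lexicon | None = None
) -> list[EntityMention]:
    """Tokenise, featurise, Viterbi-decode, and collect mentions."""
    tokens = tokenize(text) if isinstance(text, str) else list(text)
    if not tokens:
        return []
    tags = model.predict_tags(tokens, lexicon)
    return bio_decode(tokens, tags)


# ---------------------------------------------------------------- evaluation


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    r = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    f = harmonic_f1(p, r)
    return p, r, f


def harmonic_f1(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def macro_average(per_class: dict[str, tuple[float, float, float]]) -> tuple[float, float, float]:
    """Unweighted mean of per-class (precision, recall, F1) triples.

    This is the aggregation behind the summary column of a per-class
    metric table.
    """
    ps = [v[0] for v in per_class.values()]
    rs = [v[1] for v in per_class.values()]
    fs = [v[2] for v in per_class.values()]
    k = len(per_class)
    return (sum(ps) / k, sum(rs) / k, sum(fs) / k)


@dataclass
class EvalResult:
    counts: dict[str, tuple[int, int, int]]  # label -> (tp, fp, fn)
    per_class: dict[str, tuple[float, float, float]]  # label -> (P, R, F1), 0-100
    macro_precision: float
    macro_recall: float
    macro_f1: float
    micro_precision: float
    micro_recall: float
    micro_f1: float

    def as_table(self) -> str:
        lines = [f"{'label':<8}{'P':>8}{'R':>8}{'F1':>8}{'tp':>6}{'fp':>6}{'fn':>6}"]
        for label in LABELS:
            p, r, f = self.per_class[label]
            tp, fp, fn = self.counts[label]
            lines.append(f"{label:<8}{p:>8.2f}{r:>8.2f}{f:>8.2f}{tp:>6}{fp:>6}{fn:>6}")
        lines.append(
            f"{'macro':<8}{self.macro_precision:>8.2f}{self.macro_recall:>8.2f}"
            f"{self.macro_f1:>8.2f}"
        )
        lines.append(
            f"{'micro':<8}{self.micro_precision:>8.2f}{self.micro_recall:>8.2f}"
            f"{self.micro_f1:>8.2f}"
        )
        return "\n".join(lines)


def evaluate_ner(gold, predicted) -> EvalResult:
    """Strict span-level evaluation: a prediction counts as correct only if
    (start, end, label) all match a gold mention.

    ``gold`` and ``predicted`` are parallel lists of per-record mention
    lists.  Reports per-class and both macro (unweighted mean over the
    three labels) and micro (pooled counts) averages on the 0-100 scale.
    """
    if len(gold) != len(predicted):
        raise NerError("gold and predicted must have the same number of records")
    tp = {x: 0 for x in LABELS}
    fp = {x: 0 for x in LABELS}
    fn = {x: 0 for x in LABELS}
    for g_ms, p_ms in zip(gold, predicted):
        g_set = {(m.start, m.end, m.label) for m in _check_disjoint(g_ms)}
        p_set = {(m.start, m.end, m.label) for m in _check_disjoint(p_ms)}
        for s, e, x in p_set:
            if (s, e, x) in g_set:
                tp[x] += 1
            else:
                fp[x] += 1
        for s, e, x in g_set - p_set:
            fn[x] += 1
    per_class = {x: _prf(tp[x], fp[x], fn[x]) for x in LABELS}
    mp, mr, mf = macro_average(per_class)
    pooled = _prf(sum(tp.values()), sum(fp.values()), sum(fn.values()))
    return EvalResult(
        counts={x: (tp[x], fp[x], fn[x]) for x in LABELS},
        per_class=per_class,
        macro_precision=mp,
        macro_recall=mr,
        macro_f1=mf,
        micro_precision=pooled[0],
        micro_recall=pooled[1],
        micro_f1=pooled[2],
    )


# ------------------------------------------------------------ entity linking


def similarity(a: str, b: str) -> float:
    """Normalized string similarity in [0, 1]."""
    return difflib.SequenceMatcher(None, a, b).ratio()


def link_mentions(
    mentions, graph, fuzzy_threshold: float = 0.85
) -> list[EntityMention]:
    """Link mention surfaces to graph nodes of the matching entity type.

    Resolution order per mention: exact canonical name, then alias, then
    best fuzzy match with similarity >= ``fuzzy_threshold`` among nodes of
    the etype implied by the label.  Unresolved mentions keep
    ``link_method='unlinked'``.
    """
    out = []
    by_etype: dict[str, list] = {}
    for m in mentions:
        etype = LABEL_TO_ETYPE[m.label]
        node = graph.node_by_name(m.surface)
        if node is not None and node.etype == etype:
            method = "exact" if node.name == m.surface else "alias"
            out.append(
                EntityMention(m.start, m.end, m.label, m.surface, node.id, method)
            )
            continue
        if etype not in by_etype:
            by_etype[etype] = graph.nodes_of_type(etype)
        best_id, best_sim = None, 0.0
        for cand in by_etype[etype]:
            for label in (cand.name, *cand.aliases):
                sim = similarity(m.surface, label)
                if sim > best_sim or (sim == best_sim and best_id is not None and cand.id < best_id):
                    best_id, best_sim = cand.id, sim
        if best_id is not None and best_sim >= fuzzy_threshold:
            out.append(
                EntityMention(m.start, m.end, m.label, m.surface, best_id, "fuzzy")
            )
        else:
            out.append(
                EntityMention(m.start, m.end, m.label, m.surface, None, "unlinked")
            )
    return out
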