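"""String relaxation and abbreviation resolution applied before lookup.

``relax`` produces the key used by the relaxed dictionary levels: the text is
Unicode-normalized (NFC), lower-cased, de-pluralized token by token, and then
stripped of punctuation *and* internal whitespace, so that spelling variants
such as "alpha-keto esters" and "alpha-ketoester" collide on one key.  Greek
letters and other non-punctuation symbols are preserved: they are
case-meaningful parts of chemical names.

``find_abbreviations`` implements the Schwartz–Hearst short-form/long-form
pairing rules: a candidate short form appears in parentheses, its long form
is searched in the preceding window of ``min(|SF|+5, 2*|SF|)`` words, and
characters are matched right to left with the first short-form character
required to start a long-form word.  Greek letters are expanded to their
spelled names during matching only (so "amyloid beta (Abeta-like SFs)" pair),
while the returned map keeps the original surface strings.
"""

from __future__ import annotations

import unicodedata
from typing import Callable, Optional

from .ontology_io import Mention

__all__ = ["relax", "lemmatize_plural", "find_abbreviations", "expand_mention"]

#: punctuation removed under the restricted mode: the dash/parenthesis/comma
#: families only (including common Unicode dashes)
_LISTED_PUNCT = set("-(),‐‑‒–—―")

_GREEK_NAMES = {
    "α": "alpha", "β": "beta", "γ": "gamma", "δ": "delta",
    "ε": "epsilon", "κ": "kappa", "λ": "lambda", "μ": "mu",
    "σ": "sigma", "ω": "omega",
}


def lemmatize_plural(token: str) -> str:
    """Strip an English plural ending from one lower-case token.

    Only noun pluralization is undone (no stemming): chemical meaning such as
    trailing "-ic"/"-ous" endings must survive.  Short tokens (3 characters
    or fewer) and tokens ending in ``ss``/``us``/``is`` are left alone.
    """
    if len(token) <= 3 or not token.endswith("s"):
        return token
    if token.endswith("sses"):
        return token[:-2]
    if token.endswith("ies") and len(token) > 4:
        return token[:-3] + "y"
    if token.endswith(("xes", "zes", "ches", "shes", "ses")):
        return token[:-2]
    if token.endswith(("ss", "us", "is")):
        return token
    return token[:-1]


def _is_punct(ch: str, mode: str) -> bool:
    if mode == "listed":
        return ch in _LISTED_PUNCT
    return unicodedata.category(ch).startswith("P")


def _relax_once(text: str, punctuation: str) -> str:
    text = unicodedata.normalize("NFC", text).lower()
    tokens = [lemmatize_plural(tok) for tok in text.split()]
    joined = "".join(tokens)
    return "".join(ch for ch in joined if not _is_punct(ch, punctuation) and not ch.isspace())


def relax(text: str, punctuation: str = "all") -> str:
    """Relaxed-match key: lower-case, de-pluralize, drop punctuation and spaces.

    ``punctuation="all"`` (default) removes every Unicode punctuation
    character; ``"listed"`` removes only dashes, parentheses and commas.
    Applied to a fixed point (joining tokens can expose a new trailing
    plural), so ``relax(relax(x)) == relax(x)`` always holds.
    """
    out = _relax_once(text, punctuation)
    while True:
        again = _relax_once(out, punctuation)
        if again == out:
            return out
        out = again


# ---------------------------------------------------------------------------
# Schwartz-Hearst abbreviation pairing
# ---------------------------------------------------------------------------


def _expand_greek(text: str) -> tuple[str, list[int]]:
    """Spell out Greek letters; returns the expansion and a map back to source indexes."""
    out: list[str] = []
    back: list[int] = []
    for i, ch in enumerate(text):
        rep = _GREEK_NAMES.get(ch.lower(), ch)
        out.append(rep)
        back.extend([i] * len(rep))
    return "".join(out), back


def _valid_short_form(sf: str) -> bool:
    if not 2 <= len(sf) <= 10:
        return False
    if len(sf.split()) > 2:
        return False
    if not any(ch.isalpha() for ch in sf):
        return False
    return sf[0].isalnum()


def _find_best_long_form(short: str, long: str) -> Optional[str]:
    """Right-to-left character matching per Schwartz & Hearst."""
    exp_short, _ = _expand_greek(short)
    exp_long, back = _expand_greek(long)
    s = len(exp_short) - 1
    l = len(exp_long) - 1
    while s >= 0:
        c = exp_short[s].lower()
        if not c.isalnum():
            s -= 1
            continue
        while (l >= 0 and exp_long[l].lower() != c) or (
            s == 0 and l > 0 and exp_long[l - 1].isalnum()
        ):
            l -= 1
        if l < 0:
            return None
        l -= 1
        s -= 1
    start = back[l + 1] if l + 1 < len(back) else 0
    return long[start:]


def find_abbreviations(doc_text: str) -> dict[str, str]:
    """Schwartz-Hearst abbreviation map ``{short form: long form}`` for one document.

    ``doc_text`` should be the full title+abstract so that definitions
    introduced anywhere in the document resolve mentions in the title.
    """
    pairs: dict[str, str] = {}
    pos = doc_text.find("(")
    while pos != -1:
        close = doc_text.find(")", pos + 1)
        if close == -1:
            break
        inner = doc_text[pos + 1 : close].strip()
        if _valid_short_form(inner):
            words = doc_text[:pos].split()
            window = min(len(inner) + 5, 2 * len(inner))
            candidate = " ".join(words[-window:]) if words else ""
            if candidate:
                long_form = _find_best_long_form(inner, candidate)
                # a long form no shorter than its abbreviation and not
                # containing it is the usual sanity condition
                if long_form and len(long_form) >= len(inner) and inner not in long_form.split():
                    pairs.setdefault(inner, long_form)
        pos = doc_text.find("(", close + 1)
    return pairs


def expand_mention(
    mention: Mention,
    abbrevs: dict[str, str],
    case_sensitive: bool = True,
) -> Mention:
    """Rewrite the mention's lookup text when its surface is a known short form.

    The surface string and span are left untouched for reporting; only
    ``lookup_text`` changes.  Short-form matching is case-sensitive by
    default because chemical acronym case is meaningful.
    """
    key = mention.text
    if case_sensitive:
        long_form = abbrevs.get(key)
    else:
        folded = {k.lower(): v for k, v in abbrevs.items()}
        long_form = folded.get(key.lower())
    if long_form is not None:
        mention.lookup_text = long_form
    return mention
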