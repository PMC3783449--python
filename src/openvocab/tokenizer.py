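"""Emoticon-aware tokenization of social-media text.

Social-media messages are full of emoticons (``:-)``, ``<3``, ``^_^``) that
generic tokenizers shred into punctuation fragments.  The tokenizer here keeps
them intact as single tokens, splits remaining punctuation from words, and
lowercases alphabetic tokens so that casing variants pool into one feature.
URLs, @-mentions and hashtags survive as single tokens: under an
open-vocabulary analysis nothing is deleted a priori.

No stemming, lemmatization, spelling correction or sentence splitting is
performed; surface forms (including elongations like "soooo") are the unit of
analysis.
"""

from __future__ import annotations

import re
from typing import Iterable, List

__all__ = ["tokenize", "EMOTICON_PATTERNS", "build_tokenizer"]

# Western emoticons: optional "reversed" brows, eyes, optional nose, mouth —
# plus the mirrored form.  Eastern-style faces and hearts are separate entries.
EMOTICON_PATTERNS: List[str] = [
    r"[<>]?[:;=8xX][\-o\*']?[\)\]\(\[dDpP/\\\}\{@\|]",   # :-) ;) :D :P :/ x(
    r"[<>]?[:;=8][\-o\*']?3(?!\d)",                      # :3 cat face, not 8:30
    r"[\)\]\(\[dDpP/\\\}\{@\|][\-o\*']?[:;=8][<>]?",      # (-: reversed
    r"<3+",                                               # hearts <3 <33
    r"\^[_\-\.]*\^",                                      # ^_^ ^^ ^-^
    r"[oO0>TtUu\-][_\.][oO0<TtUu\-]",                     # o_O T_T -_- u_u
    r"[:;=8][\-o\*']?[sS\$&]",                            # :s :-$
]

_URL = r"(?:https?://\S+|www\.[^\s,]+)"
_MENTION = r"@\w+"
_HASHTAG = r"#\w+"
# Words may contain internal apostrophes/hyphens ("don't", "co-op").
_WORD = r"[\w]+(?:['’\-][\w]+)*"


def build_tokenizer(extra_emoticons: Iterable[str] = ()) -> re.Pattern:
    """Compile the token-scanning pattern.

    Parameters
    ----------
    extra_emoticons:
        Additional emoticon regexes (one pattern per entry), e.g. loaded from
        a supplement file with one pattern per line.  They are matched with
        the same priority as the built-in battery.
    """
    emoticons = list(extra_emoticons) + EMOTICON_PATTERNS
    parts = [
        "(?P<url>%s)" % _URL,
        "(?P<emoticon>%s)" % "|".join("(?:%s)" % p for p in emoticons),
        "(?P<mention>%s)" % _MENTION,
        "(?P<hashtag>%s)" % _HASHTAG,
        "(?P<word>%s)" % _WORD,
        r"(?P<punct>\S)",
    ]
    return re.compile("|".join(parts), re.UNICODE)


_DEFAULT = build_tokenizer()


def tokenize(text: str, pattern: re.Pattern | None = None) -> List[str]:
    """Split ``text`` into tokens, preserving emoticons as single tokens.

    Alphabetic tokens (words, mentions, hashtags) are lowercased; emoticons,
    URLs and punctuation are left untouched.  Punctuation runs are split into
    single-character tokens ("!!" -> ["!", "!"]).  Empty input yields an
    empty list.
    """
    if pattern is None:
        pattern = _DEFAULT
    tokens: List[str] = []
    for m in pattern.finditer(text):
        surface = m.group(0)
        kind = m.lastgroup
        if kind in ("word", "mention", "hashtag"):
            surface = surface.lower()
        tokens.append(surface)
    return tokens


def load_emoticon_supplement(path) -> List[str]:
    """Read one emoticon regex pattern per line, skipping blanks/#comments."""
    patterns = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line and not line.startswith("#"):
                patterns.append(line)
    return patterns
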