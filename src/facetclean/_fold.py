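"""Fixed ASCII folding table for Latin-1 and Latin Extended-A characters.

A deterministic, platform-independent transliteration used by every key
function. Characters outside the table pass through unchanged; no locale or
Unicode-normalisation machinery is involved.
"""

_GROUPS = [
    ("àáâãäåāăą", "a"),
    ("èéêëēĕėęě", "e"),
    ("ìíîïĩīĭįı", "i"),
    ("òóôõöøōŏő", "o"),
    ("ùúûüũūŭůűų", "u"),
    ("ýÿŷ", "y"),
    ("çćĉċč", "c"),
    ("ďđ", "d"),
    ("ĝğġģ", "g"),
    ("ĥħ", "h"),
    ("ĵ", "j"),
    ("ķ", "k"),
    ("ĺļľŀł", "l"),
    ("ñńņňŉ", "n"),
    ("ŕŗř", "r"),
    ("śŝşš", "s"),
    ("ţťŧ", "t"),
    ("ŵ", "w"),
    ("źżž", "z"),
    ("æ", "ae"),
    ("œ", "oe"),
    ("ß", "ss"),
    ("þ", "th"),
    ("ð", "dh"),
]

_TABLE: dict[int, str] = {}
for _chars, _ascii in _GROUPS:
    for _ch in _chars:
        _TABLE[ord(_ch)] = _ascii
        _up = _ch.upper()
        if len(_up) == 1:  # ß uppercases to two characters; keep lowercase only
            _TABLE[ord(_up)] = _ascii.upper()


def fold(value: str) -> str:
    """Transliterate accented Latin characters to plain ASCII."""
    return value.translate(_TABLE)
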