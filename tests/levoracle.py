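"""Independent edit-distance oracle: the plain recursive definition
(memoized for speed), kept free of the two-row dynamic programme it
checks."""

from functools import cache


@cache
def lev_recursive(a: str, b: str) -> int:
    if not a:
        return len(b)
    if not b:
        return len(a)
    return min(
        lev_recursive(a[1:], b) + 1,
        lev_recursive(a, b[1:]) + 1,
        lev_recursive(a[1:], b[1:]) + (a[0] != b[0]),
    )
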