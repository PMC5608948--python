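"""Shared assertions for comparisons against published table values."""


def matches_printed(value: float, printed: float, dp: int) -> bool:
    """True when ``value`` agrees with a published number at its printed
    precision, allowing either round-half or truncation conventions (both
    occur in typeset tables)."""
    scale = 10**dp
    rounded = round(value * scale) / scale
    truncated = int(value * scale) / scale
    return abs(rounded - printed) < 1e-9 or abs(truncated - printed) < 1e-9
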