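"""Deterministic fan-out of a single study seed into per-stage child seeds.

A run is reproducible from one integer: every module that consumes randomness
receives ``child_seed(seed, offset)`` with a documented, fixed offset, so any
stage can be re-run in isolation.
"""

_MOD = 2**31


def child_seed(seed: int, offset: int) -> int:
    """Derive a child seed from a global seed and a fixed stage offset."""
    return (int(seed) * 1_000_003 + int(offset) * 7_919 + 12_345) % _MOD
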