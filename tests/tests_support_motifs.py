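"""Shared fixture generator: synthetic NBD constructs with planted motifs.

The background alphabet is disjoint from every motif pattern so that the
scanner's leftmost-match semantics cannot be confounded by chance hits.
"""
BACKGROUND = "NRWYCP"


def _bg(rng, n):
    return "".join(rng.choice(list(BACKGROUND), size=n))


def planted_nbd(rng):
    """One synthetic NBD; returns (sequence, {motif name: planted start})."""
    parts = []
    pos = {}

    def emit(s):
        parts.append(s)

    def here():
        return sum(map(len, parts))

    emit(_bg(rng, int(rng.integers(5, 30))))
    pos["WalkerA"] = here()
    emit("GPSGSGKST")
    emit(_bg(rng, int(rng.integers(25, 55))))
    pos["Qloop"] = here()
    emit("Q")
    emit(_bg(rng, int(rng.integers(20, 60))))
    pos["ABCsignature"] = here()
    emit("LSGGQ")
    emit(_bg(rng, int(rng.integers(10, 40))))
    pos["WalkerB"] = here()
    emit("ILLLDE")
    wb_end = here()
    emit(_bg(rng, int(rng.integers(4, 12))))
    pos["Dloop"] = here()
    emit("SALD")
    h_at = wb_end + int(rng.integers(25, 45))
    emit(_bg(rng, h_at - here()))
    pos["Hloop"] = here()
    emit("H")
    emit(_bg(rng, 15))
    return "".join(parts), pos
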