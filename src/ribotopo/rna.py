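"""rRNA expansion-segment hairpin and kissing-loop analysis.

Folding is base-pair maximization (Nussinov-style dynamic programming)
over Watson-Crick plus GU wobble pairs with a minimum hairpin-loop
length.  This is deliberately not a thermodynamic model: the quantities
of interest here — does a segment fold as a stem-loop, how GC-rich is its
terminal loop, can two such loops pair with each other — only need the
combinatorics of nested pairing, which the DP solves exactly and which is
exactly testable against exhaustive enumeration.

Kissing interactions are scored as the longest contiguous antiparallel
run of complementary bases over all sliding registers of two loops
(bulges are not modelled).  A hairpin whose terminal loop scores highly
against itself is flagged self-complementary: two copies of it can form
the reciprocal loop-loop contact of a C2 homodimer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

RNA_ALPHABET = set("AUGC")
WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
GU_PAIRS = {("G", "U"), ("U", "G")}
COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

DEFAULT_MIN_LOOP = 3
DEFAULT_SELF_THRESHOLD = 0.75  # fraction of loop length


def _validate(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - RNA_ALPHABET
    if not seq:
        raise ValueError("empty sequence")
    if bad:
        raise ValueError(f"invalid RNA characters: {sorted(bad)}")
    return seq


def _can_pair(a: str, b: str, allow_gu: bool = True) -> bool:
    return (a, b) in WC_PAIRS or (allow_gu and (a, b) in GU_PAIRS)


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(_validate(seq)))


def gc_fraction(seq: str) -> float:
    seq = _validate(seq)
    return sum(c in "GC" for c in seq) / len(seq)


@dataclass(frozen=True)
class Hairpin:
    """A stem-loop: nested pair list, terminal stem, loop interval."""

    sequence: str
    pairs: tuple  # all base pairs of the optimal structure, (i, j) with i < j
    stem: tuple  # contiguous outermost->innermost helix closing the loop
    loop: tuple  # 0-based half-open interval of the terminal loop
    pair_count: int  # DP optimum over the whole sequence

    @property
    def loop_seq(self) -> str:
        return self.sequence[self.loop[0] : self.loop[1]]

    @property
    def loop_gc(self) -> float:
        return gc_fraction(self.loop_seq) if self.loop_seq else 0.0

    @property
    def dot_bracket(self) -> str:
        s = ["."] * len(self.sequence)
        for i, j in self.pairs:
            s[i], s[j] = "(", ")"
        return "".join(s)


def _nussinov_table(seq: str, min_loop: int, allow_gu: bool) -> list[list[int]]:
    n = len(seq)
    table = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = table[i][j - 1]
            for k in range(i, j - min_loop):
                if _can_pair(seq[k], seq[j], allow_gu):
                    left = table[i][k - 1] if k > i else 0
                    inner = table[k + 1][j - 1]
                    cand = left + 1 + inner
                    if cand > best:
                        best = cand
            table[i][j] = best
    return table


def _traceback(seq, table, i, j, min_loop, allow_gu, pairs):
    while i < j:
        if j - i <= min_loop:
            return
        if table[i][j] == table[i][j - 1]:
            j -= 1
            continue
        for k in range(i, j - min_loop):
            if _can_pair(seq[k], seq[j], allow_gu):
                left = table[i][k - 1] if k > i else 0
                if left + 1 + table[k + 1][j - 1] == table[i][j]:
                    pairs.append((k, j))
                    if k > i:
                        _traceback(seq, table, i, k - 1, min_loop, allow_gu, pairs)
                    i, j = k + 1, j - 1
                    break
        else:  # pragma: no cover - table/traceback mismatch cannot happen
            raise AssertionError("traceback failed")


def fold_hairpin(seq: str, min_loop: int = DEFAULT_MIN_LOOP, allow_gu: bool = True) -> Hairpin:
    """Fold a sequence by base-pair maximization; extract the terminal
    stem-loop.

    ``pair_count`` is the DP optimum (hairpin loops >= ``min_loop``).  The
    stem/loop come from the traceback: among the structure's hairpin loops
    the one closed by the longest contiguous helix is taken as *the*
    terminal stem-loop (ties: 5'-most).  An unpaired sequence yields an
    empty stem with the whole sequence as loop.
    """
    seq = _validate(seq)
    n = len(seq)
    table = _nussinov_table(seq, min_loop, allow_gu)
    pairs: list[tuple[int, int]] = []
    _traceback(seq, table, 0, n - 1, min_loop, allow_gu, pairs)
    pairs.sort()
    pair_set = set(pairs)

    # hairpin loops: pairs with nothing paired strictly inside
    best_stem: list[tuple[int, int]] = []
    best_loop = (0, n)
    for (i, j) in pairs:
        if any(i < a < j for (a, b) in pairs if (a, b) != (i, j)):
            continue
        stem = [(i, j)]
        while (stem[-1][0] - 1, stem[-1][1] + 1) in pair_set:
            stem.append((stem[-1][0] - 1, stem[-1][1] + 1))
        stem.reverse()  # outermost first
        if len(stem) > len(best_stem) or (
            len(stem) == len(best_stem) and best_stem and stem[0][0] < best_stem[0][0]
        ):
            best_stem = stem
            best_loop = (i + 1, j)
    return Hairpin(
        sequence=seq,
        pairs=tuple(pairs),
        stem=tuple(best_stem),
        loop=best_loop,
        pair_count=table[0][n - 1] if n > 1 else 0,
    )


@dataclass(frozen=True)
class KissingRegister:
    """Best antiparallel loop-loop pairing between two loops."""

    loop_a: str
    loop_b: str
    best_offset: int
    paired_positions: tuple  # (index in a, index in b) of the best run
    score: int  # length of the longest contiguous complementary run
    allow_gu: bool


def kissing_score(loop_a: str, loop_b: str, allow_gu: bool = False) -> KissingRegister:
    """Maximum contiguous antiparallel complementary run over all registers.

    Loop *a* is read 5'->3' against loop *b* read 3'->5' (the geometry of
    a kissing interaction); the register slides over all relative offsets,
    and within each register the longest contiguous complementary run is
    scored.  Symmetric in its arguments.
    """
    a = _validate(loop_a)
    b = _validate(loop_b)
    rb = b[::-1]
    na, nb = len(a), len(rb)
    best_score = 0
    best_offset = 0
    best_run: tuple = ()
    for offset in range(-(nb - 1), na):
        run: list[tuple[int, int]] = []
        for ia in range(max(0, offset), min(na, offset + nb)):
            ib_rev = ia - offset
            ib = nb - 1 - ib_rev  # position in the original b
            if _can_pair(a[ia], rb[ib_rev], allow_gu):
                run.append((ia, ib))
                if len(run) > best_score:
                    best_score = len(run)
                    best_offset = offset
                    best_run = tuple(run)
            else:
                run = []
    return KissingRegister(
        loop_a=a,
        loop_b=b,
        best_offset=best_offset,
        paired_positions=best_run,
        score=best_score,
        allow_gu=allow_gu,
    )


def self_kissing(
    hairpin: Hairpin | str,
    allow_gu: bool = False,
    threshold: float = DEFAULT_SELF_THRESHOLD,
) -> tuple[int, bool]:
    """Score a loop against itself; flag self-complementary loops.

    A flagged loop can pair with a second copy of itself — the reciprocal
    kissing contact that holds a C2 ribosome homodimer together.
    """
    loop = hairpin.loop_seq if isinstance(hairpin, Hairpin) else _validate(hairpin)
    if not loop:
        return 0, False
    score = kissing_score(loop, loop, allow_gu=allow_gu).score
    return score, score >= threshold * len(loop)


def coerce_rna(seq: str, record_id: str = "?") -> str:
    """Uppercase and coerce T->U with a logged warning; reject ambiguity codes."""
    seq = seq.upper()
    if "T" in seq:
        logger.warning("record %s: DNA alphabet detected, coercing T->U", record_id)
        seq = seq.replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"record {record_id}: unsupported characters {sorted(bad)}")
    return seq


def species_scan(
    fasta_path,
    min_loop: int = DEFAULT_MIN_LOOP,
    allow_gu: bool = False,
    threshold: float = DEFAULT_SELF_THRESHOLD,
) -> pd.DataFrame:
    """Fold every expansion-segment record of a FASTA file and score its
    terminal loop for self-kissing potential.

    One row per record: hairpin propensity (stem pairs relative to the
    sequence's pairing capacity), loop length and GC content, self-kissing
    score, and the self-complementarity flag.  GU wobble in the *kissing*
    register is off by default (folding always allows it).
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {fasta_path}")
    rows = []
    for rec in records:
        seq = coerce_rna(str(rec.seq), rec.id)
        hp = fold_hairpin(seq, min_loop=min_loop)
        score, flagged = self_kissing(hp, allow_gu=allow_gu, threshold=threshold)
        rows.append(
            {
                "record": rec.id,
                "length": len(seq),
                "pair_count": hp.pair_count,
                "stem_length": len(hp.stem),
                "hairpin_propensity": 2 * hp.pair_count / len(seq),
                "loop_length": len(hp.loop_seq),
                "loop_gc": round(hp.loop_gc, 4),
                "self_kissing_score": score,
                "self_complementary": flagged,
                "dot_bracket": hp.dot_bracket,
            }
        )
    return pd.DataFrame(rows)
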