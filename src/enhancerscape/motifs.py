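"""Known-motif enrichment of enhancer sequences.

A PWM (position weight matrix) is scored as log2 odds against a
background base composition; a window is a hit when its score reaches a
fraction (default 0.8) of the maximum attainable score, both strands
scanned. Enrichment of a foreground sequence set against a background
set is a one-sided Fisher exact test on the 2x2 table of
sequences-with-at-least-one-hit, which is robust to hit clustering
within a sequence. Motifs are ranked ascending by p — the structural
analog of ranking candidate transcription factors (e.g. the AP-1 family
binding the TPA-response element TGACTCA) by known-motif significance.

De-novo motif discovery is out of scope; motifs come in as JASPAR text.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "PWM",
    "EnrichmentResult",
    "read_jaspar",
    "write_jaspar",
    "read_fasta",
    "write_fasta",
    "scan",
    "enrich",
    "make_background",
    "dinucleotide_counts",
    "pwm_from_consensus",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

SeqRecordT = tuple[str, str]  # (name, sequence)


@dataclass
class PWM:
    """Per-position base probabilities with derived log2-odds scores."""

    motif_id: str
    tf_name: str
    matrix: np.ndarray  # (length, 4) probabilities
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.background = np.asarray(self.background, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (length, 4)")
        if self.matrix.shape[0] < 4:
            raise ValueError("PWM length must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must each sum to 1")
        # log-odds in log2; probabilities are pseudocounted upstream so
        # zeros only arise from a hand-built degenerate matrix
        with np.errstate(divide="ignore"):
            self.log_odds = np.log2(self.matrix / self.background)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))


@dataclass
class EnrichmentResult:
    motif_id: str
    tf_name: str
    fg_hits: int
    fg_total: int
    bg_hits: int
    bg_total: int
    p_value: float
    rank: int | None = None


def read_jaspar(path: str | Path, pseudocount: float = 0.5,
                background: np.ndarray | None = None) -> list[PWM]:
    """Parse JASPAR text (">ID NAME" + 4 base rows of counts).

    Counts become probabilities with ``pseudocount`` added per cell.
    """
    background = (np.full(4, 0.25) if background is None
                  else np.asarray(background, dtype=np.float64))
    pwms: list[PWM] = []
    header: str | None = None
    rows: dict[str, list[float]] = {}

    def flush() -> None:
        nonlocal header, rows
        if header is None:
            return
        if set(rows) != set(_BASES):
            raise ValueError(f"motif {header}: need rows for A, C, G, T")
        lengths = {len(v) for v in rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"motif {header}: row-length mismatch")
        counts = np.array([rows[b] for b in _BASES], dtype=np.float64).T
        if np.any(counts < 0):
            raise ValueError(f"motif {header}: negative count")
        counts = counts + pseudocount
        probs = counts / counts.sum(axis=1, keepdims=True)
        parts = header.split(None, 1)
        motif_id = parts[0]
        tf_name = parts[1] if len(parts) > 1 else motif_id
        pwms.append(PWM(motif_id, tf_name, probs, background))
        header, rows = None, {}

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
            else:
                base = line[0].upper()
                if base not in _BASE_INDEX:
                    raise ValueError(f"unexpected row {line[:20]!r}")
                body = line[1:].strip().lstrip("[").rstrip("]")
                rows[base] = [float(x) for x in body.split()]
    flush()
    return pwms


def write_jaspar(pwms: list[PWM], path: str | Path, scale: float = 100.0) -> None:
    """Write PWMs as JASPAR text (probabilities scaled to pseudo-counts)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id} {pwm.tf_name}\n")
            for bi, base in enumerate(_BASES):
                vals = " ".join(f"{v * scale:.4f}" for v in pwm.matrix[:, bi])
                fh.write(f"{base} [ {vals} ]\n")


def read_fasta(path: str | Path) -> list[SeqRecordT]:
    records: list[SeqRecordT] = []
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    records.append((name, "".join(chunks)))
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        records.append((name, "".join(chunks)))
    return records


def write_fasta(records: list[SeqRecordT], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    idx = np.full(len(seq), 4, dtype=np.int8)  # 4 = N / unknown
    for base, i in _BASE_INDEX.items():
        idx[np.frombuffer(seq.encode(), dtype=np.uint8)
            == ord(base)] = i
    return idx


def _window_scores(idx: np.ndarray, score_table: np.ndarray) -> np.ndarray:
    """Scores of every window of length len(score_table) over idx codes."""
    L = score_table.shape[0]
    n = len(idx) - L + 1
    if n <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    return score_table[np.arange(L)[None, :], windows].sum(axis=1)


def scan(
    sequences: list[SeqRecordT],
    pwm: PWM,
    threshold_fraction: float = 0.8,
) -> dict[str, list[tuple[int, str, float]]]:
    """Scan both strands; a window is a hit at >= fraction of max score.

    Returns {sequence name: [(offset on + strand, strand, score), ...]}.
    N bases score as the minimum base log-odds at that position.
    """
    if not (0 < threshold_fraction <= 1):
        raise ValueError("threshold_fraction must be in (0, 1]")
    L = len(pwm)
    # column 4 handles N: worst base at that position
    table = np.hstack([pwm.log_odds, pwm.log_odds.min(axis=1, keepdims=True)])
    threshold = threshold_fraction * pwm.max_score
    hits: dict[str, list[tuple[int, str, float]]] = {}
    for name, seq in sequences:
        out: list[tuple[int, str, float]] = []
        if len(seq) < L:
            warnings.warn(f"sequence {name} shorter than motif {pwm.motif_id}")
            hits[name] = out
            continue
        fwd = _window_scores(_encode(seq), table)
        for pos in np.nonzero(fwd >= threshold)[0]:
            out.append((int(pos), "+", float(fwd[pos])))
        rev = _window_scores(_encode(reverse_complement(seq)), table)
        for pos in np.nonzero(rev >= threshold)[0]:
            out.append((len(seq) - L - int(pos), "-", float(rev[pos])))
        hits[name] = sorted(out)
    return hits


def enrich(
    fg: list[SeqRecordT],
    bg: list[SeqRecordT],
    pwms: list[PWM],
    threshold_fraction: float = 0.8,
) -> list[EnrichmentResult]:
    """Rank motifs by one-sided Fisher p on sequence-level hit tables."""
    if not fg or not bg:
        raise ValueError("foreground and background must be non-empty")
    results = []
    for pwm in pwms:
        fg_hits = sum(1 for h in scan(fg, pwm, threshold_fraction).values() if h)
        bg_hits = sum(1 for h in scan(bg, pwm, threshold_fraction).values() if h)
        table = [[fg_hits, len(fg) - fg_hits], [bg_hits, len(bg) - bg_hits]]
        _, p = stats.fisher_exact(table, alternative="greater")
        results.append(
            EnrichmentResult(
                motif_id=pwm.motif_id,
                tf_name=pwm.tf_name,
                fg_hits=fg_hits,
                fg_total=len(fg),
                bg_hits=bg_hits,
                bg_total=len(bg),
                p_value=float(p),
            )
        )
    results.sort(key=lambda r: (r.p_value, r.motif_id))
    for i, r in enumerate(results):
        r.rank = i + 1
    return results


def dinucleotide_counts(seq: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(seq) - 1):
        pair = seq[i:i + 2]
        counts[pair] = counts.get(pair, 0) + 1
    return counts


def _dinucleotide_shuffle_one(seq: str, rng: np.random.Generator) -> str:
    """Altschul–Erikson shuffle preserving exact dinucleotide counts."""
    if len(seq) <= 2:
        return seq
    edges: dict[str, list[str]] = {}
    for i in range(len(seq) - 1):
        edges.setdefault(seq[i], []).append(seq[i + 1])
    last = seq[-1]
    vertices = list(edges)
    for _ in range(10000):
        # choose a candidate terminal edge per non-final vertex
        last_edge = {}
        for v in vertices:
            if v == last:
                continue
            last_edge[v] = edges[v][rng.integers(len(edges[v]))]
        # the chosen edges must form a tree rooted at `last`
        ok = True
        for v in last_edge:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - practically unreachable for DNA
        raise RuntimeError("dinucleotide shuffle failed to converge")
    shuffled_edges = {}
    for v in vertices:
        rest = list(edges[v])
        if v in last_edge:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        shuffled_edges[v] = rest + ([last_edge[v]] if v in last_edge else [])
    out = [seq[0]]
    pointers = {v: 0 for v in vertices}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled_edges[cur][pointers[cur]]
        pointers[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def make_background(
    fg: list[SeqRecordT],
    method: str = "dinucleotide_shuffle",
    seed: int = 0,
    genome: dict[str, str] | None = None,
    exclude: list[tuple[str, int, int]] | None = None,
) -> list[SeqRecordT]:
    """Build a background set: dinucleotide shuffle or genomic sampling.

    ``dinucleotide_shuffle`` preserves each sequence's exact dinucleotide
    count vector (Euler-path shuffle) and length. ``genomic_sample``
    draws length-matched windows from ``genome`` avoiding ``exclude``
    intervals. Deterministic given ``seed``.
    """
    if not fg:
        raise ValueError("foreground must be non-empty")
    rng = np.random.default_rng(seed)
    if method == "dinucleotide_shuffle":
        return [
            (f"shuf_{name}", _dinucleotide_shuffle_one(seq, rng))
            for name, seq in fg
        ]
    if method == "genomic_sample":
        if genome is None:
            raise ValueError("genomic_sample requires a genome FASTA dict")
        excluded = exclude or []
        chroms = sorted(genome)
        out = []
        for name, seq in fg:
            want = len(seq)
            for _ in range(1000):
                chrom = chroms[rng.integers(len(chroms))]
                limit = len(genome[chrom]) - want
                if limit <= 0:
                    continue
                start = int(rng.integers(limit))
                if any(c == chrom and start < e and s < start + want
                       for c, s, e in excluded):
                    continue
                out.append((f"bg_{name}", genome[chrom][start:start + want]))
                break
            else:
                raise RuntimeError("could not sample a background window")
        return out
    raise ValueError(f"unknown background method {method!r}")


def pwm_from_consensus(
    motif_id: str,
    tf_name: str,
    consensus: str,
    match_prob: float = 0.85,
) -> PWM:
    """A sharp PWM concentrated on a consensus string."""
    mat = np.full((len(consensus), 4), (1 - match_prob) / 3)
    for i, base in enumerate(consensus.upper()):
        mat[i, _BASE_INDEX[base]] = match_prob
    return PWM(motif_id, tf_name, mat)
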