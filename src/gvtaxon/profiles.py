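"""Position-specific scoring profiles for protein families.

A profile is a trimmed-alignment-derived log-odds matrix (columns x 20
amino acids, in bits) with affine gap penalties, scored against query
proteins by local (Smith–Waterman/Gotoh) alignment.  E-values come from a
Gumbel null fitted to the scores of seeded random sequences drawn from
the background composition at profile build time; absolute e-values are
therefore calibrated to this scorer, not to any external profile-HMM
package, and all e-value thresholds downstream are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

DEFAULT_GAP_OPEN = 4.0  # bits
DEFAULT_GAP_EXTEND = 0.5  # bits
DEFAULT_N_NULL = 200


class AlignmentError(ValueError):
    pass


def trim_alignment(alignment: Mapping[str, str], gap_threshold: float = 0.1) -> dict[str, str]:
    """Keep columns whose non-gap fraction is at least ``gap_threshold``.

    This is the gap-threshold column filter of alignment-trimming tools
    (``-gt`` semantics): a column survives iff the fraction of sequences
    with a residue there is >= the threshold.  Row order is preserved and
    the operation is idempotent.
    """
    if not alignment:
        raise AlignmentError("empty alignment")
    rows = list(alignment.values())
    width = len(rows[0])
    if width == 0:
        raise AlignmentError("zero-length alignment")
    if any(len(r) != width for r in rows):
        raise AlignmentError("ragged alignment rows")
    n = len(rows)
    keep = []
    for c in range(width):
        nongap = sum(1 for r in rows if r[c] not in "-.")
        if nongap / n >= gap_threshold:
            keep.append(c)
    return {name: "".join(row[c] for c in keep) for name, row in alignment.items()}


@dataclass
class Profile:
    gvog_id: str
    matrix: np.ndarray  # (length, 20) log-odds bits
    background: np.ndarray  # (20,)
    gap_open: float
    gap_extend: float
    n_source_sequences: int
    null_loc: float | None = None
    null_scale: float | None = None

    @property
    def length(self) -> int:
        return int(self.matrix.shape[0])

    def as_dict(self) -> dict:
        return {
            "gvog_id": self.gvog_id,
            "length": self.length,
            "alphabet": AA_ORDER,
            "matrix": self.matrix.tolist(),
            "background": self.background.tolist(),
            "gap_open": self.gap_open,
            "gap_extend": self.gap_extend,
            "n_source_sequences": self.n_source_sequences,
            "null_loc": self.null_loc,
            "null_scale": self.null_scale,
        }


@dataclass
class ProfileHit:
    protein_id: str
    gvog_id: str
    bitscore: float
    evalue: float
    query_aligned_fraction: float
    is_best_for_genome: bool = False


def encode(seq: str) -> np.ndarray:
    idx = np.array([_AA_INDEX.get(c, -1) for c in seq.upper()], dtype=np.int64)
    return idx[idx >= 0]


def build_profile(
    gvog_id: str,
    aligned_members: Mapping[str, str],
    gap_threshold: float = 0.1,
    pseudocount: float = 1.0,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    calibrate: bool = True,
    n_null: int = DEFAULT_N_NULL,
    seed: int = 0,
) -> Profile:
    """Log-odds profile from an alignment (trimmed at ``gap_threshold``).

    Column frequencies are smoothed with ``pseudocount`` total counts
    distributed according to the background (uniform over 20 residues),
    then converted to bits against that background.
    """
    trimmed = trim_alignment(aligned_members, gap_threshold)
    width = len(next(iter(trimmed.values())))
    if width == 0:
        raise AlignmentError(f"{gvog_id}: alignment fully trimmed away")
    bg = np.full(20, 1.0 / 20.0)
    counts = np.zeros((width, 20))
    for row in trimmed.values():
        for c, ch in enumerate(row.upper()):
            i = _AA_INDEX.get(ch)
            if i is not None:
                counts[c, i] += 1.0
    nongap = counts.sum(axis=1, keepdims=True)
    freqs = (counts + pseudocount * bg) / (nongap + pseudocount)
    matrix = np.log2(freqs / bg)
    prof = Profile(gvog_id, matrix, bg, gap_open, gap_extend, len(trimmed))
    if calibrate:
        _calibrate_null(prof, n_null=n_null, seed=seed)
    return prof


def _calibrate_null(profile: Profile, n_null: int, seed: int) -> None:
    """Fit a Gumbel (location/scale) to scores of background-drawn sequences."""
    rng = np.random.default_rng(seed)
    length = max(profile.length, 10)
    scores = np.empty(n_null)
    for i in range(n_null):
        seq_idx = rng.choice(20, size=length, p=profile.background)
        scores[i], _, _ = _local_align(seq_idx, profile)
    loc, scale = stats.gumbel_r.fit(scores)
    profile.null_loc = float(loc)
    profile.null_scale = float(max(scale, 1e-9))


def _local_align(query_idx: np.ndarray, profile: Profile) -> tuple[float, int, int]:
    """Gotoh local alignment of an encoded query against the profile.

    Rows of the DP are profile columns, columns are query positions.
    Returns (score, query_start, query_end) with a 0-based half-open query
    interval covered by the best local alignment.  Alongside each DP cell
    we carry the query index where its local alignment started, so the
    aligned query fraction falls out without a traceback matrix.
    """
    m = int(query_idx.size)
    L = profile.length
    if m == 0 or L == 0:
        return 0.0, 0, 0
    go, ge = profile.gap_open, profile.gap_extend
    NEG = -1e30
    sub_all = profile.matrix[:, query_idx].tolist()  # L rows of m floats

    H = [0.0] * (m + 1)
    SH = list(range(m + 1))
    E = [NEG] * (m + 1)  # vertical: profile column consumed, query gapped
    SE = [0] * (m + 1)
    best = 0.0
    best_start = 0
    best_end = 0
    for r in range(L):
        sub = sub_all[r]
        prevH, prevSH = H, SH
        H = [0.0] * (m + 1)
        SH = [0] * (m + 1)
        F = NEG  # horizontal: query residue consumed, profile gapped
        SF = 0
        for c in range(1, m + 1):
            ph = prevH[c - 1]
            d = ph + sub[c - 1]
            sd = prevSH[c - 1] if ph > 0.0 else c - 1
            fo = H[c - 1] - go
            fe = F - ge
            if fo >= fe:
                F, SF = fo, SH[c - 1]
            else:
                F = fe
            eo = prevH[c] - go
            ee = E[c] - ge
            if eo >= ee:
                E[c], SE[c] = eo, prevSH[c]
            else:
                E[c] = ee
            h, sh = d, sd
            if E[c] > h:
                h, sh = E[c], SE[c]
            if F > h:
                h, sh = F, SF
            if h < 0.0:
                h, sh = 0.0, c
            H[c] = h
            SH[c] = sh
            if h > best:
                best, best_start, best_end = h, sh, c
    return float(best), int(best_start), int(best_end)


def search_profile(
    protein_id: str,
    sequence: str,
    profile: Profile,
) -> ProfileHit:
    """Best local alignment of a protein against a profile.

    Reports the bit score, a Gumbel-calibrated e-value, and the fraction
    of the query covered by the alignment.  A query with no positive-score
    alignment yields a sentinel hit with an e-value above any cutoff.
    """
    qidx = encode(sequence)
    if qidx.size == 0:
        return ProfileHit(protein_id, profile.gvog_id, 0.0, np.inf, 0.0)
    score, qstart, qend = _local_align(qidx, profile)
    if score <= 0:
        return ProfileHit(protein_id, profile.gvog_id, 0.0, np.inf, 0.0)
    qaf = (qend - qstart) / qidx.size
    if profile.null_loc is not None:
        ev = float(stats.gumbel_r.sf(score, loc=profile.null_loc,
                                     scale=profile.null_scale))
    else:
        ev = float(np.exp2(-score))
    return ProfileHit(protein_id, profile.gvog_id, score, ev, qaf)
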