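"""Twin-tag demultiplexing and paired-end merging.

A read pair belongs to a PCR replicate iff both 7-nt tags match that
replicate's twin tag; pairs whose two tags belong to different replicates are
tag jumps and are binned separately (the whole point of twin tagging). After
tag assignment the degenerate Leray primers are located (IUPAC-aware, up to
2 mismatches) and clipped; both amplicon orientations are tried.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqs import iupac_mismatches, revcomp
from .simulate import PRIMER_F, PRIMER_R, ReadPair

TAG_LEN = 7


class ConfigError(ValueError):
    pass


@dataclass
class TagScheme:
    """unit_id -> twin (forward, reverse) tags; units are sample#rep pairs."""

    tags: dict[str, tuple[str, str]]
    primer_fwd: str = PRIMER_F
    primer_rev: str = PRIMER_R
    max_tag_mismatches: int = 0
    max_primer_mismatches: int = 2

    def __post_init__(self) -> None:
        lens = {len(t) for pair in self.tags.values() for t in pair}
        if lens and lens != {TAG_LEN}:
            raise ConfigError("all tags must be 7 nt")
        for unit, (f, r) in self.tags.items():
            if f != r:
                raise ConfigError(f"twin-tag mode requires forward == reverse tag ({unit})")
        seen = [f for f, _ in self.tags.values()]
        if len(set(seen)) != len(seen):
            raise ConfigError("tag collision: tags must be unique across units")

    @classmethod
    def from_plans(cls, plans, **kw) -> "TagScheme":
        tags = {}
        for plan in plans:
            for rep, tag in enumerate(plan.tags, start=1):
                tags[f"{plan.sample_id}#{rep}"] = (tag, tag)
        return cls(tags=tags, **kw)

    def lookup(self, observed: str) -> str | None:
        """Unit whose tag matches ``observed`` within max_tag_mismatches."""
        best, best_d, tie = None, self.max_tag_mismatches + 1, False
        for unit, (tag, _) in self.tags.items():
            d = sum(a != b for a, b in zip(tag, observed))
            if d < best_d:
                best, best_d, tie = unit, d, False
            elif d == best_d:
                tie = True
        return None if tie or best_d > self.max_tag_mismatches else best


def split_unit(unit: str) -> tuple[str, int]:
    sample, rep = unit.rsplit("#", 1)
    return sample, int(rep)


@dataclass
class TrimmedPair:
    read_id: str
    fwd_seq: str
    fwd_qual: str
    rev_seq: str
    rev_qual: str


@dataclass
class DemuxResult:
    assigned: dict[str, list[TrimmedPair]]
    jump: list[str] = field(default_factory=list)        # read ids
    unassigned: list[str] = field(default_factory=list)  # read ids (incl. primer failures)
    n_no_primer: int = 0

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.assigned.values())

    def report(self):
        import pandas as pd

        rows = [
            {"unit": u, "sample": split_unit(u)[0], "replicate": split_unit(u)[1],
             "assigned": len(v)}
            for u, v in sorted(self.assigned.items())
        ]
        df = pd.DataFrame(rows, columns=["unit", "sample", "replicate", "assigned"])
        df.attrs["jump"] = len(self.jump)
        df.attrs["unassigned"] = len(self.unassigned)
        return df


def _find_primer(seq: str, primer: str, max_mm: int) -> int | None:
    """Primer must sit right after the tag; returns clip length or None."""
    if len(seq) < len(primer):
        return None
    return len(primer) if iupac_mismatches(primer, seq) <= max_mm else None


def demultiplex(pairs: list[ReadPair], scheme: TagScheme) -> DemuxResult:
    """Assign pairs to units; conserve counts across assigned/jump/unassigned."""
    out = DemuxResult(assigned={u: [] for u in scheme.tags})
    for pair in pairs:
        t1, t2 = pair.r1_seq[:TAG_LEN], pair.r2_seq[:TAG_LEN]
        u1, u2 = scheme.lookup(t1), scheme.lookup(t2)
        if u1 is None or u2 is None:
            out.unassigned.append(pair.read_id)
            continue
        if u1 != u2:
            out.jump.append(pair.read_id)
            continue
        body1, qual1 = pair.r1_seq[TAG_LEN:], pair.r1_qual[TAG_LEN:]
        body2, qual2 = pair.r2_seq[TAG_LEN:], pair.r2_qual[TAG_LEN:]
        # orientation A: R1 carries the forward primer; B: reads swapped
        clip_f = _find_primer(body1, scheme.primer_fwd, scheme.max_primer_mismatches)
        clip_r = _find_primer(body2, scheme.primer_rev, scheme.max_primer_mismatches)
        if clip_f is not None and clip_r is not None:
            out.assigned[u1].append(
                TrimmedPair(pair.read_id, body1[clip_f:], qual1[clip_f:],
                            body2[clip_r:], qual2[clip_r:])
            )
            continue
        clip_f = _find_primer(body2, scheme.primer_fwd, scheme.max_primer_mismatches)
        clip_r = _find_primer(body1, scheme.primer_rev, scheme.max_primer_mismatches)
        if clip_f is not None and clip_r is not None:
            out.assigned[u1].append(
                TrimmedPair(pair.read_id, body2[clip_f:], qual2[clip_f:],
                            body1[clip_r:], qual1[clip_r:])
            )
            continue
        out.n_no_primer += 1
        out.unassigned.append(pair.read_id)
    return out


# ---------------------------------------------------------------------------
# pair merging


@dataclass
class MergeParams:
    min_overlap: int = 20
    max_overlap_mismatch_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ConfigError("min_overlap must be >= 1")


_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i


def _overlap_scores(a: str, b: str) -> np.ndarray:
    """matches[ov] = identical bases when the last ov nt of a overlap the first ov of b."""
    xa = _ENC[np.frombuffer(a.encode(), dtype=np.uint8)]
    xb = _ENC[np.frombuffer(b.encode(), dtype=np.uint8)]
    la, lb = len(xa), len(xb)
    matches = np.zeros(min(la, lb) + 1)
    for base in range(4):
        fa = (xa == base).astype(np.float64)
        fb = (xb == base).astype(np.float64)
        corr = np.correlate(fb, fa, mode="full")  # lag index la-1+s, s = offset of a in b
        # overlap ov corresponds to a starting at offset -(ov) from b start:
        # a[la-ov+i] vs b[i] -> shift s = -(la-ov) -> index la-1-(la-ov) = ov-1
        matches[1:] += corr[: min(la, lb)]
    return matches


def merge_pair(
    fwd: str, fq: str, rev: str, rq: str, params: MergeParams
) -> tuple[str, str] | None:
    """Overlap-merge one trimmed pair; None if no acceptable overlap exists.

    The reverse read is reverse-complemented, the overlap minimizing the
    mismatch rate (ties to the longest) is chosen, and conflicting overlap
    bases are resolved in favor of the higher-quality call.
    """
    b = revcomp(rev)
    bq = rq[::-1]
    matches = _overlap_scores(fwd, b)
    ovs = np.arange(len(matches))
    with np.errstate(invalid="ignore"):
        rates = 1.0 - matches / np.maximum(ovs, 1)
    valid = (ovs >= params.min_overlap) & (rates <= params.max_overlap_mismatch_rate)
    if not valid.any():
        return None
    cand = np.flatnonzero(valid)
    best = cand[np.lexsort((cand, -np.round(rates[cand] * 1e12)))][-1]
    ov = int(best)
    head, head_q = fwd[: len(fwd) - ov], fq[: len(fwd) - ov]
    tail, tail_q = b[ov:], bq[ov:]
    mid, mid_q = [], []
    for i in range(ov):
        x, qx = fwd[len(fwd) - ov + i], fq[len(fq) - ov + i]
        y, qy = b[i], bq[i]
        if x == y:
            mid.append(x)
            mid_q.append(max(qx, qy))
        elif qx >= qy:
            mid.append(x)
            mid_q.append(qx)
        else:
            mid.append(y)
            mid_q.append(qy)
    return head + "".join(mid) + tail, head_q + "".join(mid_q) + tail_q


def merge_pairs(
    pairs: list[TrimmedPair], params: MergeParams | None = None
) -> tuple[list[tuple[str, str, str]], int]:
    """Merge all pairs; returns ((read_id, seq, qual), ...) and rejection count."""
    params = params or MergeParams()
    merged, rejected = [], 0
    for p in pairs:
        res = merge_pair(p.fwd_seq, p.fwd_qual, p.rev_seq, p.rev_qual, params)
        if res is None:
            rejected += 1
        else:
            merged.append((p.read_id, res[0], res[1]))
    return merged, rejected
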