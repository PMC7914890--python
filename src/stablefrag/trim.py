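"""Read cleaning: 3' quality trimming, adapter removal, length filtering.

Single-end reads whose 3' adapter was not found are rejected, because the
RNA insert then extends beyond the read and its 3' end is unknown. In
paired-end mode the adapter overlap minimum drops to one base to maximise
adapter removal; occasional overtrimming of genuine insert bases is
accepted (the mate covers the loss after pseudo-SE merging).
"""
from __future__ import annotations

from dataclasses import dataclass

from .records import FastqRead, TrimOutcome


class InputError(ValueError):
    pass


@dataclass
class TrimConfig:
    adapter3: str
    quality_cutoff: int = 30
    min_length: int = 18
    max_error_rate: float = 0.1
    min_overlap_pe: int = 1
    min_overlap_se: int = 3


def quality_trim_3prime(read: FastqRead, cutoff: int = 30) -> FastqRead:
    """BWA-style running-sum 3' quality trim.

    Subtract ``cutoff`` from each quality, accumulate partial sums from the 3'
    end and cut at the position minimising the sum; no cut if the minimum
    partial sum is non-negative.
    """
    s = 0
    best = 0
    cut = len(read.quals)
    for i in range(len(read.quals) - 1, -1, -1):
        s += read.quals[i] - cutoff
        if s < best:
            best = s
            cut = i
    return read.truncated(cut)


def trim_adapter(
    read: FastqRead,
    adapter3: str,
    min_overlap: int = 1,
    max_error_rate: float = 0.1,
) -> tuple[FastqRead, bool]:
    """Remove the longest read suffix matching an adapter prefix.

    Matching allows substitutions only, at most ``floor(rate * overlap)`` of
    them; ties go to the longest overlap (leftmost cut). The adapter may occur
    in full inside the read (read-through), in which case everything from the
    match start is removed.
    """
    bases = read.bases
    n = len(bases)
    alen = len(adapter3)
    for i in range(n):
        ov = min(n - i, alen)
        if ov < min_overlap:
            break
        allowed = int(max_error_rate * ov)
        mism = 0
        for a, b in zip(bases[i : i + ov], adapter3[:ov]):
            if a != b:
                mism += 1
                if mism > allowed:
                    break
        if mism <= allowed:
            return read.truncated(i), True
    return read, False


def _trim_one(read: FastqRead, min_overlap: int, cfg: TrimConfig) -> TrimOutcome:
    qt = quality_trim_3prime(read, cfg.quality_cutoff)
    n_quality = len(read) - len(qt)
    at, found = trim_adapter(qt, cfg.adapter3, min_overlap, cfg.max_error_rate)
    return TrimOutcome("kept", at, found, n_quality, len(qt) - len(at))


def trim_read(read_or_pair, mode: str, config: TrimConfig):
    """Clean one SE read or PE pair; returns one or two TrimOutcomes.

    Status rules: SE reads without an adapter hit are ``rejected_untrimmed``;
    any read shorter than ``min_length`` after trimming is ``rejected_short``
    (in PE mode a short mate rejects the whole pair).
    """
    if mode == "SE":
        out = _trim_one(read_or_pair, config.min_overlap_se, config)
        if not out.adapter_found:
            out.status = "rejected_untrimmed"
        elif len(out.read) < config.min_length:
            out.status = "rejected_short"
        return out
    r1, r2 = read_or_pair
    if r1.id != r2.id:
        raise InputError(f"mate ID mismatch: {r1.id!r} vs {r2.id!r}")
    out1 = _trim_one(r1, config.min_overlap_pe, config)
    out2 = _trim_one(r2, config.min_overlap_pe, config)
    if len(out1.read) < config.min_length or len(out2.read) < config.min_length:
        out1.status = out2.status = "rejected_short"
    return out1, out2


def trim_library(reads, mode: str, config: TrimConfig):
    """Clean a whole library.

    ``reads`` is a list of FastqRead (SE) or of (R1, R2) pairs (PE). Returns
    (kept, too_short, untrimmed, tallies); kept mirrors the input structure,
    sidecar lists are flat reads. The conservation identity
    ``kept + rejected_short + rejected_untrimmed == input`` holds in read units.
    """
    kept, too_short, untrimmed = [], [], []
    tallies = {"input_reads": 0, "kept_reads": 0, "rejected_short": 0, "rejected_untrimmed": 0}
    for item in reads:
        if mode == "SE":
            tallies["input_reads"] += 1
            out = trim_read(item, "SE", config)
            if out.status == "kept":
                kept.append(out.read)
                tallies["kept_reads"] += 1
            elif out.status == "rejected_short":
                too_short.append(out.read)
                tallies["rejected_short"] += 1
            else:
                untrimmed.append(out.read)
                tallies["rejected_untrimmed"] += 1
        else:
            tallies["input_reads"] += 2
            out1, out2 = trim_read(item, "PE", config)
            if out1.status == "kept":
                kept.append((out1.read, out2.read))
                tallies["kept_reads"] += 2
            else:
                too_short.extend([out1.read, out2.read])
                tallies["rejected_short"] += 2
    return kept, too_short, untrimmed, tallies
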