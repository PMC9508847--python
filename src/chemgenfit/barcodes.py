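"""Up-tag barcode counting from FASTQ reads.

A read is assigned to the unique strain whose barcode matches the length-L
substring at a fixed offset within ``max_mismatches`` substitutions; reads
equidistant from two barcodes at the minimal distance are ambiguous and
discarded. Only substitutions are considered (barcodes are short and fixed
length), and no quality filtering is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

_AMBIGUOUS = -2

REPORT_FIELDS = ("total", "assigned", "ambiguous", "unmatched", "too_short")


@dataclass
class CountingReport:
    per_sample: pd.DataFrame  # samples x REPORT_FIELDS

    def conserved(self) -> bool:
        df = self.per_sample
        return bool((df["assigned"] + df["ambiguous"] + df["unmatched"]
                     + df["too_short"] == df["total"]).all())


def _validate_catalog(catalog: pd.DataFrame) -> int:
    tags = catalog["uptag"]
    lengths = tags.str.len().unique()
    if len(lengths) != 1:
        raise ValueError(f"mixed barcode lengths in catalog: {sorted(lengths)}")
    if tags.duplicated().any():
        dups = tags[tags.duplicated()].tolist()
        raise ValueError(f"duplicate barcodes in catalog: {dups[:5]}")
    return int(lengths[0])


def _mismatch1_index(tags: list[str]) -> dict[str, int]:
    """Map each 1-substitution neighbor to its strain index, or AMBIGUOUS."""
    neigh: dict[str, int] = {}
    for i, tag in enumerate(tags):
        for pos in range(len(tag)):
            for base in "ACGT":
                if base == tag[pos]:
                    continue
                key = tag[:pos] + base + tag[pos + 1:]
                prev = neigh.get(key)
                if prev is None:
                    neigh[key] = i
                elif prev != i:
                    neigh[key] = _AMBIGUOUS
        # a barcode that is itself within distance 1 of another barcode is
        # resolved by the exact index, which is consulted first
    return neigh


def _encode(seqs: list[str], L: int) -> np.ndarray:
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    return arr.reshape(len(seqs), L)


def count_uptags(fastq_by_sample: dict[str, str], catalog: pd.DataFrame,
                 max_mismatches: int = 1, offset: int = 0
                 ) -> tuple[pd.DataFrame, CountingReport]:
    """Count barcode reads per strain for each sample.

    ``fastq_by_sample`` maps sample id -> FASTQ path (optionally gzipped).
    Returns the strains x samples count matrix (every catalog strain present,
    zero rows included) and a per-sample counting report satisfying
    ``assigned + ambiguous + unmatched + too_short == total``.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    if offset < 0:
        raise ValueError("offset must be >= 0")
    L = _validate_catalog(catalog)
    tags = list(catalog["uptag"])
    exact = {tag: i for i, tag in enumerate(tags)}
    neigh = _mismatch1_index(tags) if max_mismatches >= 1 else {}
    cat_codes = _encode(tags, L) if max_mismatches >= 2 else None

    n_strains = len(tags)
    samples = list(fastq_by_sample)
    counts = np.zeros((n_strains, len(samples)), dtype=np.int64)
    report_rows = []
    for j, sample in enumerate(samples):
        total = assigned = ambiguous = unmatched = too_short = 0
        pending: list[str] = []  # only used for the brute-force >=2 path
        with pysam.FastxFile(str(fastq_by_sample[sample])) as fh:
            for read in fh:
                total += 1
                seq = read.sequence
                if seq is None or len(seq) < offset + L:
                    too_short += 1
                    continue
                sub = seq[offset:offset + L].upper()
                idx = exact.get(sub)
                if idx is not None:
                    counts[idx, j] += 1
                    assigned += 1
                    continue
                if max_mismatches == 0:
                    unmatched += 1
                    continue
                hit = neigh.get(sub)
                if hit is None:
                    if max_mismatches >= 2:
                        pending.append(sub)
                    else:
                        unmatched += 1
                elif hit == _AMBIGUOUS:
                    ambiguous += 1
                else:
                    counts[hit, j] += 1
                    assigned += 1
        if pending:
            reads = _encode(pending, L)
            for start in range(0, reads.shape[0], 2048):
                chunk = reads[start:start + 2048]
                # (reads, strains) Hamming distances
                dist = (chunk[:, None, :] != cat_codes[None, :, :]).sum(axis=2)
                best = dist.min(axis=1)
                n_best = (dist == best[:, None]).sum(axis=1)
                for r in range(chunk.shape[0]):
                    if best[r] > max_mismatches:
                        unmatched += 1
                    elif n_best[r] > 1:
                        ambiguous += 1
                    else:
                        counts[int(dist[r].argmin()), j] += 1
                        assigned += 1
        report_rows.append({"sample": sample, "total": total,
                            "assigned": assigned, "ambiguous": ambiguous,
                            "unmatched": unmatched, "too_short": too_short})
    cdf = pd.DataFrame(counts, index=pd.Index(list(catalog["gene"]), name="gene"),
                       columns=samples)
    report = CountingReport(pd.DataFrame(report_rows).set_index("sample"))
    return cdf, report
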