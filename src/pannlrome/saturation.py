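"""Rarefaction (saturation) analysis of orthogroup discovery and of
diversity recovery across accession subsets.

OG discovery is bootstrapped by drawing accession subsets without
replacement (the question is how many OGs a panel of k accessions reveals,
so replacement would misstate it), for every size from 2 to the panel size.
The discovery curve reports, per size, the mean fraction of all OGs with at
least one member in the subset, percentile confidence bounds, and the mean
size of the OGs that remain undiscovered.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import CodonAlignment
from .popgen import NAN, neutrality_stats


def rarefy_ogs(matrix: pd.DataFrame, reps: int = 1000,
               seed: int = 0) -> pd.DataFrame:
    """Bootstrap OG discovery curves from an OG x accession count matrix.

    Returns a DataFrame with columns size, mean_fraction, lo, hi (2.5/97.5
    percentiles) and mean_undiscovered_size.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    present = (matrix.values > 0)
    n_og, n_acc = present.shape
    if n_acc < 2:
        raise ValueError("need at least 2 accessions")
    og_sizes = present.sum(axis=1)
    rng = np.random.default_rng(seed)

    rows = []
    for k in range(2, n_acc + 1):
        fracs = np.empty(reps)
        undisc = np.empty(reps)
        for r in range(reps):
            cols = rng.choice(n_acc, size=k, replace=False)
            found = present[:, cols].any(axis=1)
            fracs[r] = found.mean()
            missed = ~found
            undisc[r] = og_sizes[missed].mean() if missed.any() else 0.0
        rows.append((k, fracs.mean(),
                     float(np.percentile(fracs, 2.5)),
                     float(np.percentile(fracs, 97.5)),
                     undisc.mean()))
    return pd.DataFrame(rows, columns=[
        "size", "mean_fraction", "lo", "hi", "mean_undiscovered_size"])


def saturation_point(curve: pd.DataFrame, target: float = 0.95) -> int | None:
    """Smallest subset size whose mean discovery fraction reaches the
    target; None if never reached."""
    hit = curve.loc[curve["mean_fraction"] >= target, "size"]
    return int(hit.iloc[0]) if len(hit) else None


def rarefy_diversity(alignments: dict[str, CodonAlignment],
                     accession_of_gene: dict[str, str],
                     reps: int = 100, seed: int = 0) -> pd.DataFrame:
    """Fraction of nucleotide and haplotype diversity recovered by
    accession subsets of each size.

    For each subset, the mean pi and mean haplotype diversity are
    recomputed over the OG alignments with at least two sampled members and
    divided by the full-panel means. Subset sizes start at 2.
    """
    accessions = sorted({accession_of_gene[g]
                         for aln in alignments.values() for g in aln.ids})
    n_acc = len(accessions)
    if n_acc < 2:
        raise ValueError("need at least 2 accessions")

    def mean_divs(acc_subset: set[str] | None):
        pis, hds = [], []
        for aln in alignments.values():
            if acc_subset is None:
                sub = aln
            else:
                keep = [g for g in aln.ids
                        if accession_of_gene[g] in acc_subset]
                if len(keep) < 2:
                    continue
                sub = aln.subset_rows(keep)
            st = neutrality_stats(sub)
            pis.append(st.pi)
            hds.append(st.hap_div)
        if not pis:
            return NAN, NAN
        return float(np.mean(pis)), float(np.mean(hds))

    full_pi, full_hd = mean_divs(None)
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(2, n_acc + 1):
        fp = np.empty(reps)
        fh = np.empty(reps)
        for r in range(reps):
            subset = set(rng.choice(accessions, size=k, replace=False))
            pi_k, hd_k = mean_divs(subset)
            fp[r] = pi_k / full_pi if full_pi else NAN
            fh[r] = hd_k / full_hd if full_hd else NAN
        rows.append((k, float(np.nanmean(fp)), float(np.nanmean(fh))))
    return pd.DataFrame(rows, columns=[
        "size", "pi_fraction", "hap_div_fraction"])
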