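"""Diversity and neutrality statistics on codon alignments.

Per-OG statistics: nucleotide diversity (pi), segregating sites, Watterson's
theta, haplotype diversity and number of haplotypes, Tajima's D, Fu & Li's
D* and F* (star variants — no outgroup is available within an orthogroup),
Ramos-Onsins & Rozas' R2 and Strobeck's S. Gapped columns are removed before
counting (complete deletion) by default; pairwise deletion is available for
the distance-based quantities via the ``deletion`` switch.

Statistics that are undefined for an alignment (e.g. Tajima's D with no
segregating sites) are reported as NaN — an explicit not-a-value sentinel,
never zero.

Domain-aware statistics re-use the same machinery on the concatenation of
alignment columns claimed by one domain, where each column's domain is the
majority vote over the members' per-residue annotations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections import Counter, defaultdict

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .models import CodonAlignment, DomainInterval

NAN = float("nan")

_GAP_CHARS = frozenset("-N?")


@dataclass
class NeutralityStats:
    n: int
    L: int
    S: int
    pi: float
    theta_w: float
    hap_div: float
    K: int
    tajima_d: float
    fu_li_d_star: float
    fu_li_f_star: float
    r2: float
    strobeck_s: float
    eta_s: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _empty_stats(n: int = 0) -> NeutralityStats:
    return NeutralityStats(n=n, L=0, S=0, pi=NAN, theta_w=NAN, hap_div=NAN,
                           K=0, tajima_d=NAN, fu_li_d_star=NAN,
                           fu_li_f_star=NAN, r2=NAN, strobeck_s=NAN, eta_s=0)


def _harmonic(n: int, power: int = 1) -> float:
    return sum(1.0 / i ** power for i in range(1, n))


def tajima_d(n: int, S: int, pi_count: float) -> float:
    """Tajima's D from sample size, segregating sites and the mean pairwise
    difference count (per locus)."""
    if S == 0 or n < 2:
        return NAN
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return NAN
    return (pi_count - S / a1) / math.sqrt(var)


def fu_li_d_star(n: int, S: int, eta_s: int) -> float:
    """Fu & Li's D* (no outgroup), with the Simonsen et al. corrections."""
    if S == 0 or n < 3:
        return NAN
    an = _harmonic(n)
    bn = _harmonic(n, 2)
    an1 = an + 1.0 / n
    cn = 1.0 if n == 2 else 2 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
    dn = (cn + (n - 2) / (n - 1) ** 2
          + (2 / (n - 1)) * (1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n))
    v = ((n / (n - 1)) ** 2 * bn + an ** 2 * dn
         - 2 * (n * an * (an + 1)) / (n - 1) ** 2) / (an ** 2 + bn)
    u = (n / (n - 1)) * (an - n / (n - 1)) - v
    var = u * S + v * S * S
    if var <= 0:
        return NAN
    return ((n / (n - 1)) * S - an * eta_s) / math.sqrt(var)


def fu_li_f_star(n: int, S: int, eta_s: int, pi_count: float) -> float:
    """Fu & Li's F* (no outgroup), with the Simonsen et al. corrections."""
    if S == 0 or n < 3:
        return NAN
    an = _harmonic(n)
    bn = _harmonic(n, 2)
    an1 = an + 1.0 / n
    v = ((2 * n ** 3 + 110 * n ** 2 - 255 * n + 153) / (9 * n ** 2 * (n - 1))
         + 2 * (n - 1) * an / n ** 2 - 8 * bn / n) / (an ** 2 + bn)
    u = ((4 * n ** 2 + 19 * n + 3 - 12 * (n + 1) * an1)
         / (3 * n * (n - 1))) / an - v
    var = u * S + v * S * S
    if var <= 0:
        return NAN
    return (pi_count - ((n - 1) / n) * eta_s) / math.sqrt(var)


def strobeck_s(n: int, K: int, theta_hat: float) -> float:
    """Ewens-sampling probability of observing at most K haplotypes given
    the per-locus Watterson estimate. Equals 1 when theta_hat is 0."""
    if n < 1 or K < 1:
        return NAN
    if theta_hat <= 0:
        return 1.0
    # unsigned Stirling numbers of the first kind, |s(n, k)| for k=0..n
    s = np.zeros(n + 1)
    s[0] = 1.0  # |s(0,0)|; iterate to |s(n,k)|
    for m in range(1, n + 1):
        new = np.zeros(n + 1)
        new[1:] = s[:-1]
        new += (m - 1) * s
        s = new
    denom = np.prod(theta_hat + np.arange(n))
    probs = np.array([s[k] * theta_hat ** k for k in range(n + 1)]) / denom
    return float(probs[1:min(K, n) + 1].sum())


def neutrality_stats(aln: CodonAlignment,
                     deletion: str = "complete") -> NeutralityStats:
    """Compute the full statistics bundle for one codon alignment.

    ``deletion='complete'`` (default) removes every nucleotide column that
    carries a gap in any row before counting; ``'pairwise'`` keeps all
    columns and normalizes pairwise differences by per-pair comparable
    sites (distance-based statistics only).
    """
    n = aln.n
    if n < 2:
        raise ValueError("need at least 2 sequences")
    arr = np.array([list(s) for s in aln.seqs])
    gap = np.isin(arr, list(_GAP_CHARS))
    if deletion == "complete":
        keep = ~gap.any(axis=0)
        arr = arr[:, keep]
        gap = gap[:, keep]
    elif deletion != "pairwise":
        raise ValueError("deletion must be 'complete' or 'pairwise'")
    L = arr.shape[1]
    if L == 0:
        raise ValueError("no ungapped columns left in alignment")

    # segregating sites / singletons over fully-called columns
    S = 0
    eta_s = 0
    U = np.zeros(n)  # per-sequence singleton counts
    for j in range(L):
        col = arr[:, j]
        called = ~gap[:, j]
        counts = Counter(col[called])
        if len(counts) > 1:
            S += 1
            for base, c in counts.items():
                if c == 1:
                    eta_s += 1
                    U[np.flatnonzero(called & (col == base))[0]] += 1

    # pairwise differences
    total_diff = 0.0
    n_pairs = n * (n - 1) // 2
    per_site_sum = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            diffs = int((arr[i, ok] != arr[j, ok]).sum())
            total_diff += diffs
            sites = int(ok.sum())
            per_site_sum += diffs / sites if sites else 0.0
    pi_count = total_diff / n_pairs
    pi = (pi_count / L) if deletion == "complete" else per_site_sum / n_pairs

    a1 = _harmonic(n)
    theta_w_locus = S / a1
    theta_w = theta_w_locus / L

    # haplotypes on the retained columns
    haplo = Counter("".join(row) for row in arr)
    K = len(haplo)
    p = np.array(list(haplo.values())) / n
    hap_div = n * (1 - float((p ** 2).sum())) / (n - 1)

    if S > 0:
        r2 = float(np.sqrt(((U - pi_count / 2) ** 2).mean())) / S
    else:
        r2 = NAN

    return NeutralityStats(
        n=n, L=L, S=S, pi=pi, theta_w=theta_w,
        hap_div=hap_div if K > 1 else 0.0, K=K,
        tajima_d=tajima_d(n, S, pi_count),
        fu_li_d_star=fu_li_d_star(n, S, eta_s),
        fu_li_f_star=fu_li_f_star(n, S, eta_s, pi_count),
        r2=r2,
        strobeck_s=strobeck_s(n, K, theta_w_locus),
        eta_s=eta_s)


def tajima_d_null(n: int, theta: float, reps: int, seed: int,
                  length: int = 300) -> dict:
    """Empirical null moments of Tajima's D under the neutral coalescent,
    using the package's own simulator. Undefined replicates (no segregating
    sites) are excluded from the moments and counted."""
    from .simulate import simulate_neutral_alignment
    if reps < 200:
        raise ValueError("need at least 200 replicates")
    rng = np.random.default_rng(seed)
    vals = []
    n_undefined = 0
    for _ in range(reps):
        sub = int(rng.integers(0, 2 ** 31 - 1))
        aln = simulate_neutral_alignment(n, length, theta, sub)
        d = neutrality_stats(aln).tajima_d
        if math.isnan(d):
            n_undefined += 1
        else:
            vals.append(d)
    if not vals:
        return {"mean": NAN, "sd": NAN, "n_defined": 0,
                "n_undefined": n_undefined}
    return {"mean": float(np.mean(vals)), "sd": float(np.std(vals, ddof=1)),
            "n_defined": len(vals), "n_undefined": n_undefined}


# ---------------------------------------------------------------------------
# per-column domain annotation
# ---------------------------------------------------------------------------

def annotate_columns(aln: CodonAlignment,
                     domains_of_gene: dict[str, list[DomainInterval]]
                     ) -> list[str]:
    """Majority-vote domain label per codon column.

    Domain intervals are in ungapped protein (residue) coordinates. Each
    non-gap residue in a column votes for the domain covering it (the
    covering interval with the most C-terminal start wins within one gene);
    a column's label is the domain claimed by a strict majority of its
    non-gap residues, else ``none``.
    """
    labels = []
    row_domains = []
    for gid in aln.ids:
        ivals = sorted(domains_of_gene.get(gid, []),
                       key=lambda d: (d.start, d.label))
        prot_len = sum(1 for c in range(aln.n_codons)
                       if aln.row(gid)[3 * c: 3 * c + 3] != "---")
        for d in ivals:
            if d.end > prot_len:
                raise ValueError(
                    f"{gid}: domain {d.label} ends at {d.end} but protein "
                    f"has {prot_len} residues")
        row_domains.append(ivals)

    res_index = np.zeros((aln.n, aln.n_codons), dtype=int)  # 1-based, 0=gap
    for i, s in enumerate(aln.seqs):
        r = 0
        for c in range(aln.n_codons):
            if s[3 * c: 3 * c + 3] != "---":
                r += 1
                res_index[i, c] = r

    for c in range(aln.n_codons):
        votes: Counter[str] = Counter()
        n_nongap = 0
        for i in range(aln.n):
            r = res_index[i, c]
            if r == 0:
                continue
            n_nongap += 1
            cover = [d for d in row_domains[i] if d.start <= r <= d.end]
            if cover:
                best = max(cover, key=lambda d: (d.start, d.label))
                votes[best.label] += 1
        label = "none"
        if votes:
            top, cnt = votes.most_common(1)[0]
            if 2 * cnt > n_nongap:
                label = top
        labels.append(label)
    return labels


def domain_subset_stats(aln: CodonAlignment, column_labels: list[str],
                        domain: str,
                        deletion: str = "complete") -> NeutralityStats:
    """Statistics on the concatenated codon columns of one domain; a
    sentinel bundle if the domain labels no column."""
    idx = [c for c, lab in enumerate(column_labels) if lab == domain]
    if not idx:
        return _empty_stats(aln.n)
    return neutrality_stats(aln.subset_codon_columns(idx), deletion=deletion)


def invariable_codons(aln: CodonAlignment) -> tuple[int, list[int]]:
    """Codon columns identical (and gap-free) across all rows."""
    if aln.n < 2:
        raise ValueError("need at least 2 rows")
    positions = []
    for c in range(aln.n_codons):
        codons = {s[3 * c: 3 * c + 3] for s in aln.seqs}
        if len(codons) == 1 and "-" not in next(iter(codons)):
            positions.append(c)
    return len(positions), positions


# ---------------------------------------------------------------------------
# enrichment / correlation / expression
# ---------------------------------------------------------------------------

def flag_enrichment(og_flag_counts: dict[tuple[str, str], int],
                    og_sizes: dict[str, int],
                    background_flag_counts: dict[str, int],
                    universe_size: int,
                    q_max: float = 0.1) -> pd.DataFrame:
    """Hypergeometric flag enrichment per (OG, flag) with BH correction.

    ``og_flag_counts[(og, flag)]`` is the number of flagged members in the
    OG; ``background_flag_counts[flag]`` the number in the whole gene
    universe of ``universe_size``. p is the upper-tail probability of
    drawing at least that many flagged genes in a draw of OG size. Rows
    with q < ``q_max`` are marked significant.
    """
    rows = []
    for (og, flag), k in sorted(og_flag_counts.items()):
        K = background_flag_counts.get(flag, 0)
        size = og_sizes[og]
        if k > K or K > universe_size or size > universe_size:
            raise ValueError(
                f"inconsistent counts for ({og}, {flag}): k={k}, K={K}, "
                f"n={size}, N={universe_size}")
        p = float(sps.hypergeom.sf(k - 1, universe_size, K, size))
        rows.append((og, flag, k, K, size, p))
    df = pd.DataFrame(rows, columns=["og_id", "flag", "k", "K", "og_size", "p"])
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["q"] < q_max
    else:
        df["q"] = []
        df["significant"] = []
    return df


def pair_correlation(values_a, values_b) -> dict:
    """Pearson correlation and least-squares line between two per-pair
    statistic vectors. Zero variance in either vector gives NaN sentinels."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return {"r": NAN, "slope": NAN, "intercept": NAN}
    res = sps.linregress(a, b)
    return {"r": float(res.rvalue), "slope": float(res.slope),
            "intercept": float(res.intercept)}


def expression_threshold(nlr_counts, intron_counts,
                         grid_points: int = 512) -> float:
    """Minimum expression threshold from an intron-background density.

    Both count vectors are kernel-density-estimated on a shared
    log10(count+1) grid; the background density is subtracted from the NLR
    density and the lowest expression level with a positive difference is
    returned (on the original count scale). NaN if the difference is never
    positive or all counts are zero.
    """
    nlr = np.asarray(nlr_counts, dtype=float)
    bg = np.asarray(intron_counts, dtype=float)
    if nlr.size == 0 or bg.size == 0:
        raise ValueError("both count vectors must be non-empty")
    if nlr.max() == 0 and bg.max() == 0:
        return NAN
    lo_n, lo_b = np.log10(nlr + 1), np.log10(bg + 1)
    grid = np.linspace(0, max(lo_n.max(), lo_b.max()) * 1.05, grid_points)

    def density(x):
        if np.ptp(x) == 0:
            d = np.zeros_like(grid)
            d[np.argmin(np.abs(grid - x[0]))] = 1.0
            return d
        return sps.gaussian_kde(x)(grid)

    diff = density(lo_n) - density(lo_b)
    pos = np.flatnonzero(diff > 1e-12)
    if pos.size == 0:
        return NAN
    return float(10 ** grid[pos[0]] - 1)
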