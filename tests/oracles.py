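"""Independent brute-force oracles, written directly from the definitions.

These deliberately avoid the package's vectorised code paths: plain string
loops, biopython translation, and exhaustive enumeration only.
"""

import itertools

from Bio.Seq import Seq

BASES = "ACGT"
SKIP = {"-", "N"}


def brute_p_distance(a: str, b: str):
    used = diffs = 0
    for x, y in zip(a, b):
        if x in SKIP or y in SKIP:
            continue
        used += 1
        diffs += x != y
    return diffs / used


def brute_pi(seqs):
    """Mean pairwise difference per site on the shared gap/N-free columns."""
    keep = [
        i
        for i in range(len(seqs[0]))
        if all(s[i] not in SKIP for s in seqs)
    ]
    total = 0.0
    pairs = 0
    for a, b in itertools.combinations(seqs, 2):
        total += sum(a[i] != b[i] for i in keep) / len(keep)
        pairs += 1
    return total / pairs


def brute_pi_between(group_a, group_b):
    seqs = list(group_a) + list(group_b)
    keep = [
        i
        for i in range(len(seqs[0]))
        if all(s[i] not in SKIP for s in seqs)
    ]
    total = 0.0
    for a in group_a:
        for b in group_b:
            total += sum(a[i] != b[i] for i in keep) / len(keep)
    return total / (len(group_a) * len(group_b))


def brute_variable_informative(seqs):
    """(variable, informative) column index sets (1-based), ignoring gap/N
    states; columns containing any gap are excluded (complete deletion)."""
    variable, informative = set(), set()
    for i in range(len(seqs[0])):
        chars = [s[i] for s in seqs]
        if "-" in chars:
            continue
        counts = {}
        for c in chars:
            if c in SKIP:
                continue
            counts[c] = counts.get(c, 0) + 1
        if len(counts) >= 2:
            variable.add(i + 1)
            if sum(1 for v in counts.values() if v >= 2) >= 2:
                informative.add(i + 1)
    return variable, informative


def brute_diagnostic(columns_of, members, others, column_count):
    """Diagnostic (column, state) pairs for a member set, per the definition:
    all assessable members share one state absent from assessable others.
    ``columns_of`` maps record id -> aligned sequence string."""
    out = []
    for col in range(1, column_count + 1):
        member_states = {
            columns_of[m][col - 1]
            for m in members
            if columns_of[m][col - 1] not in SKIP
        }
        if len(member_states) != 1:
            continue
        (state,) = member_states
        other_states = {
            columns_of[o][col - 1]
            for o in others
            if columns_of[o][col - 1] not in SKIP
        }
        if state not in other_states:
            out.append((col, state))
    return out


def brute_fixed(columns_of, group_a, group_b, f_high, f_low, column_count,
                min_assessable=2):
    """(column, state) pairs satisfying the relaxed frequency rule."""
    out = []
    for col in range(1, column_count + 1):
        sa = [columns_of[m][col - 1] for m in group_a]
        sb = [columns_of[m][col - 1] for m in group_b]
        sa = [c for c in sa if c not in SKIP]
        sb = [c for c in sb if c not in SKIP]
        if len(sa) < min_assessable or len(sb) < min_assessable:
            continue
        for state in BASES:
            fa = sa.count(state) / len(sa)
            fb = sb.count(state) / len(sb)
            hi_a = fa > f_high or (f_high == 1 and fa == 1)
            lo_b = fb < f_low or (f_low == 0 and fb == 0)
            hi_b = fb > f_high or (f_high == 1 and fb == 1)
            lo_a = fa < f_low or (f_low == 0 and fa == 0)
            if (hi_a and lo_b) or (hi_b and lo_a):
                out.append((col, state))
    return out


# -- Nei-Gojobori oracle --------------------------------------------------


def _aa(codon):
    return str(Seq(codon).translate())


def _is_stop(codon):
    return _aa(codon) == "*"


def oracle_codon_sites(codon):
    """Synonymous-site count of one codon; stop-producing changes are left
    out of the denominator at each position."""
    s = 0.0
    for pos in range(3):
        syn = possible = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if _is_stop(mutant):
                continue
            possible += 1
            syn += _aa(mutant) == _aa(codon)
        if possible:
            s += syn / possible
    return s


def oracle_codon_differences(ca, cb):
    """(syn, nonsyn) differences averaged over minimal stop-free pathways."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        sd = nd = 0.0
        cur = ca
        ok = True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if _is_stop(nxt):
                ok = False
                break
            if _aa(cur) == _aa(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    assert paths, "oracle fixture must avoid stop-locked codon pairs"
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


def oracle_pair_kaks(seq_a, seq_b):
    """(pS, pN, S, N, sd, nd) for one in-frame gap-free codon sequence pair."""
    assert len(seq_a) == len(seq_b) and len(seq_a) % 3 == 0
    S = sd = nd = 0.0
    n_codons = len(seq_a) // 3
    for k in range(n_codons):
        ca, cb = seq_a[3 * k : 3 * k + 3], seq_b[3 * k : 3 * k + 3]
        S += (oracle_codon_sites(ca) + oracle_codon_sites(cb)) / 2
        ds, dn = oracle_codon_differences(ca, cb)
        sd += ds
        nd += dn
    N = 3 * n_codons - S
    return sd / S, nd / N, S, N, sd, nd


def brute_hudson_fst(dist_fn, groups):
    """1 - Hw/Hb from a pairwise distance callable and a label->seqs map."""
    within, between = [], []
    items = [(lab, s) for lab, seqs in groups.items() for s in seqs]
    for (la, a), (lb, b) in itertools.combinations(items, 2):
        (within if la == lb else between).append(dist_fn(a, b))
    hw = sum(within) / len(within)
    hb = sum(between) / len(between)
    return 1 - hw / hb
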