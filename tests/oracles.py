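"""Independent naive reference implementations used as test oracles.

Deliberately written as plain loops over the definitions, sharing no code
with the package implementations they check.
"""

from itertools import product

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

GAAC_GROUPS = {
    "g1": "GAVLMI", "g2": "FYW", "g3": "KRH", "g4": "DE", "g5": "STCPNQ",
}
CT_CLASSES = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")


def naive_aac(seq):
    return [seq.count(t) / len(seq) for t in ALPHABET]


def naive_gaac(seq):
    return [
        sum(seq.count(t) for t in members) / len(seq)
        for members in GAAC_GROUPS.values()
    ]


def naive_ct(seq):
    cls = {}
    for i, members in enumerate(CT_CLASSES):
        for r in members:
            cls[r] = i
    counts = {}
    for triad in product(range(7), repeat=3):
        counts[triad] = 0
    for i in range(len(seq) - 2):
        counts[(cls[seq[i]], cls[seq[i + 1]], cls[seq[i + 2]])] += 1
    f = [counts[t] for t in product(range(7), repeat=3)]
    fmin, fmax = min(f), max(f)
    if fmax == 0:
        return [0.0] * 343
    return [(fi - fmin) / fmax for fi in f]


def naive_qso(seq, matrices, w=0.1, nlag=30):
    """Direct loop evaluation: per matrix, 20 composition + nlag coupling."""
    n = len(seq)
    idx = {r: i for i, r in enumerate(ALPHABET)}
    f = [seq.count(t) / n for t in ALPHABET]
    out = []
    for mat in matrices:
        taus = []
        for d in range(1, nlag + 1):
            tau = 0.0
            for i in range(n - d):
                tau += mat[idx[seq[i]]][idx[seq[i + d]]] ** 2
            taus.append(tau)
        denom = sum(f) + w * sum(taus)
        out.extend(fr / denom for fr in f)
        out.extend(w * tau / denom for tau in taus)
    return out


def naive_auc(labels, scores):
    """Concordant-pair count over all (positive, negative) pairs; ties 0.5."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def random_sequence(rng, length):
    return "".join(rng.choice(list(ALPHABET), size=length))
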