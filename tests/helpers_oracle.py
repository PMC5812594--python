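"""Independent reference implementations used as test oracles.

Everything here is deliberately naive: explicit 1-based loops over all pair
and triple interactions per window, no cumulative sums, no vectorization, no
code shared with the package's scoring path.
"""

HYDROPHOBIC = set("VILMFY")
PATTERNS = ((3, 6), (3, 7), (4, 7), (4, 8))


def _charge(aa):
    if aa in "DE":
        return -1
    if aa in "KR":
        return 1
    return 0


def naive_window_score(seq, start, window_size, config):
    """Brute-force raw window score; ``start`` is 1-based and may be <= 0."""
    hydro_score = charged_score = 0.0
    for rule in config.network_rules:
        if rule.kind.name == "HYDROPHOBIC":
            hydro_score = rule.score
        else:
            charged_score = rule.score
    n = len(seq)
    total = 0.0
    for i in range(start, start + window_size):
        if i < 1 or i > n:
            continue  # dummy padding
        a = seq[i - 1]
        for spacing, matrix in ((3, config.matrix_i3), (4, config.matrix_i4)):
            j = i + spacing
            if j <= n:
                total += matrix.pair_score(a, seq[j - 1])
        for d1, d2 in PATTERNS:
            j, k = i + d1, i + d2
            if k <= n:
                b, c = seq[j - 1], seq[k - 1]
                if a in HYDROPHOBIC and b in HYDROPHOBIC and c in HYDROPHOBIC:
                    total += hydro_score
                elif _charge(a) * _charge(b) == -1 and _charge(b) * _charge(c) == -1:
                    total += charged_score
    return total


def naive_profile(seq, window_size, config):
    """Brute-force normalized profile, one score per residue."""
    offset = window_size // 2 + 1
    norm = config.max_window_scores[window_size]
    return [
        naive_window_score(seq, r - offset + 1, window_size, config) / norm
        for r in range(1, len(seq) + 1)
    ]
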