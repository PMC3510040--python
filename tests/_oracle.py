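"""Literal, unoptimized reference implementation of the ROH-calling rules.

Written in plain Python loops, independently of the package's vectorised
code paths, so the two can be compared on random grids. Deliberately slow
and direct: every window is enumerated, every rule is evaluated verbatim.
"""

from __future__ import annotations


def window_mean(snpbin, covered, j, w):
    vals = [snpbin[k] for k in range(j, j + w) if covered[k]]
    return sum(vals) / len(vals) if vals else None


def candidate_mask(snpbin, covered, avg, window_len, mode="anchored"):
    n = len(snpbin)
    mask = [False] * n
    if n < window_len:
        return mask
    for i in range(n):
        if mode == "anchored":
            anchors = []
            if i + window_len <= n:
                anchors.append(i)               # forward: window starts at i
            if i - window_len + 1 >= 0:
                anchors.append(i - window_len + 1)  # reverse: window ends at i
        else:
            anchors = range(max(0, i - window_len + 1), min(i, n - window_len) + 1)
        for j in anchors:
            m = window_mean(snpbin, covered, j, window_len)
            if m is not None and m < avg:
                mask[i] = True
                break
    return mask


def stretches_from_mask(mask):
    out = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def local_window_ok(snpbin, covered, a, b, i, window_len, cap):
    w = min(window_len, b - a)
    for j in range(max(a, i - w + 1), min(b - w, i) + 1):
        m = window_mean(snpbin, covered, j, w)
        if m is not None and m > cap:
            return False
    return True


def split_at(a, b, cuts):
    pieces, cur = [], a
    for i in sorted(cuts):
        if i > cur:
            pieces.append((cur, i))
        cur = i + 1
    if cur < b:
        pieces.append((cur, b))
    return pieces


def threshold_and_relaxation(stretches, snpbin, covered, avg, params, bin_size=10_000):
    mu_bin = params.mu_per_bin if params.mu_per_bin is not None else params.mu_per_bp * bin_size
    threshold = max(params.rel_threshold * avg, params.fdr_per_bin + mu_bin)
    bin_cap = params.relax_bin_cap_factor * avg
    win_cap = params.relax_window_cap_factor * avg
    out = []
    for a, b in stretches:
        nonconf = [i for i in range(a, b) if covered[i] and snpbin[i] > threshold]
        hard = [
            i for i in nonconf
            if snpbin[i] > bin_cap
            or not local_window_ok(snpbin, covered, a, b, i, params.window_len, win_cap)
        ]
        soft = [i for i in nonconf if i not in hard]
        for a2, b2 in split_at(a, b, hard):
            relaxed = [i for i in soft if a2 <= i < b2]
            keep = [snpbin[i] for i in range(a2, b2) if covered[i] and i not in relaxed]
            if keep and (not relaxed or sum(keep) / len(keep) <= threshold):
                out.append((a2, b2, frozenset(relaxed)))
            elif relaxed:
                for a3, b3 in split_at(a2, b2, relaxed):
                    if any(covered[i] for i in range(a3, b3)):
                        out.append((a3, b3, frozenset()))
    return out


def coverage_rules(stretch, covered, snpbin, bin_starts, bin_ends, params):
    a, b = stretch[0], stretch[1]
    while a < b and not covered[a]:
        a += 1
    while b > a and not covered[b - 1]:
        b -= 1
    if b <= a:
        return None
    n_unc = sum(1 for i in range(a, b) if not covered[i])
    if n_unc / (b - a) > params.max_uncovered_frac:
        return None
    start, end = bin_starts[a], bin_ends[b - 1]
    if end - start < params.min_roh_bp:
        return None
    vals = [snpbin[i] for i in range(a, b) if covered[i]]
    return (start, end, b - a, n_unc, sum(vals) / len(vals))


def classify(start, end, params):
    size = end - start
    if size < params.small_upper_bp:
        return "small"
    if size > params.large_lower_bp:
        return "large"
    return "medium"


def call_rohs(snpbin, covered, bin_starts, bin_ends, avg, params, bin_size=10_000):
    """Full literal caller for one chromosome. Returns (start, end, n_bins,
    n_uncovered, mean_snpbin, size_class) tuples."""
    mask = candidate_mask(snpbin, covered, avg, params.window_len, params.window_mode)
    stretches = stretches_from_mask(mask)
    trimmed = threshold_and_relaxation(stretches, snpbin, covered, avg, params, bin_size)
    out = []
    for st in trimmed:
        r = coverage_rules(st, covered, snpbin, bin_starts, bin_ends, params)
        if r is not None:
            out.append(r + (classify(r[0], r[1], params),))
    return out
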