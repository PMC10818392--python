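"""Independent single-loop reference implementations used as oracles.

Deliberately naive (explicit Python loops, no numpy vectorization, no
reuse of library code) so they stay independent of the implementations
they check.
"""

import math


def ref_total_displacement(ap, ml):
    total = 0.0
    for a, m in zip(ap, ml):
        total += math.sqrt(a * a + m * m)
    return total


def ref_path_length(ap, ml):
    total = 0.0
    for i in range(len(ap) - 1):
        da = ap[i + 1] - ap[i]
        dm = ml[i + 1] - ml[i]
        total += math.sqrt(da * da + dm * dm)
    return total


def ref_ellipse_area(ap, ml, scale=2.4478):
    n = len(ap)
    ma = sum(ap) / n
    mm = sum(ml) / n
    saa = sum((a - ma) ** 2 for a in ap) / (n - 1)
    smm = sum((m - mm) ** 2 for m in ml) / (n - 1)
    sam = sum((a - ma) * (m - mm) for a, m in zip(ap, ml)) / (n - 1)
    # eigenvalues of [[saa, sam], [sam, smm]] by the quadratic formula
    tr = saa + smm
    det = saa * smm - sam * sam
    disc = math.sqrt(max(tr * tr / 4 - det, 0.0))
    l1 = tr / 2 + disc
    l2 = tr / 2 - disc
    return math.pi * scale * scale * math.sqrt(max(l1, 0.0) * max(l2, 0.0))


def ref_range(x):
    return max(x) - min(x)


def ref_dispersion(x, center=True):
    n = len(x)
    mu = sum(x) / n if center else 0.0
    return math.sqrt(sum((v - mu) ** 2 for v in x) / n)


def ref_mean_velocity(x, rate):
    n = len(x)
    total = 0.0
    for i in range(n - 1):
        total += abs(x[i + 1] - x[i])
    return rate / n * total


def ref_total_mean_velocity(ap, ml, rate):
    n = len(ap)
    total = 0.0
    for i in range(n - 1):
        da = ap[i + 1] - ap[i]
        dm = ml[i + 1] - ml[i]
        total += math.sqrt(da * da + dm * dm)
    return rate / n * total


def ref_interp(t_query, ts, vs):
    """Point-by-point linear interpolation at a single time."""
    if t_query <= ts[0]:
        return vs[0]
    if t_query >= ts[-1]:
        return vs[-1]
    for i in range(len(ts) - 1):
        if ts[i] <= t_query <= ts[i + 1]:
            w = (t_query - ts[i]) / (ts[i + 1] - ts[i])
            return vs[i] * (1 - w) + vs[i + 1] * w
    raise AssertionError("unreachable")


def ref_joint_angle(p, v, d):
    u1 = [p[k] - v[k] for k in range(3)]
    u2 = [d[k] - v[k] for k in range(3)]
    n1 = math.sqrt(sum(c * c for c in u1))
    n2 = math.sqrt(sum(c * c for c in u2))
    cos = sum(a * b for a, b in zip(u1, u2)) / (n1 * n2)
    cos = min(1.0, max(-1.0, cos))
    return math.degrees(math.acos(cos))


def ref_gradient(x, dt):
    """Central differences, one-sided at the endpoints."""
    n = len(x)
    out = [0.0] * n
    out[0] = (x[1] - x[0]) / dt
    out[-1] = (x[-1] - x[-2]) / dt
    for i in range(1, n - 1):
        out[i] = (x[i + 1] - x[i - 1]) / (2 * dt)
    return out


def ref_score_dbt(trace, offsets, initial_halfwidth, narrowing_factor,
                  hold_samples, max_samples):
    """Step-by-step DBT replay, independent of the library state machine."""
    completed = 0
    round_idx = 0
    run = 0
    for i in range(min(len(trace), max_samples)):
        if round_idx >= len(offsets):
            break
        h = initial_halfwidth * narrowing_factor**round_idx
        lo = offsets[round_idx] - h
        hi = offsets[round_idx] + h
        if lo <= trace[i] <= hi:
            run += 1
        else:
            run = 0
        if run >= hold_samples:
            completed += 1
            round_idx += 1
            run = 0
    return completed
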