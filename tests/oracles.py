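"""Independent brute-force oracles kept deliberately naive.

These re-derive expected results with plain-Python enumeration so the
implementations they check can never share a code path with them.
"""

from scipy import stats


def brute_force_dmrs(probes, window=500, min_probes=2, max_gap=None):
    """Enumerate DMRs from a list of (position, significant, z, effect)
    tuples for one chromosome/family, plain lists throughout.

    Returns a list of dicts sorted by start position.
    """
    if max_gap is None:
        max_gap = window
    probes = sorted(probes, key=lambda p: p[0])
    # split the tested grid into maximal significant stretches
    stretches = []
    current = []
    for probe in probes:
        pos, significant = probe[0], probe[1]
        if not significant:
            if current:
                stretches.append(current)
            current = []
            continue
        if current and pos - current[-1][0] > max_gap:
            stretches.append(current)
            current = []
        current.append(probe)
    if current:
        stretches.append(current)

    regions = []
    for stretch in stretches:
        i = 0
        while i < len(stretch):
            j = i
            while j + 1 < len(stretch) and stretch[j + 1][0] - stretch[i][0] <= window:
                j += 1
            members = stretch[i : j + 1]
            if len(members) >= min_probes:
                zs = [m[2] for m in members]
                z_comb = sum(zs) / len(zs) ** 0.5
                regions.append(
                    {
                        "start": members[0][0],
                        "end": members[-1][0],
                        "n_probes": len(members),
                        "mean_effect": sum(m[3] for m in members) / len(members),
                        "combined_p": float(stats.norm.sf(abs(z_comb))),
                    }
                )
            i = j + 1
    return sorted(regions, key=lambda r: r["start"])
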