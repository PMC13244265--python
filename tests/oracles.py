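"""Independent brute-force re-implementations used only as test oracles.

Everything here is deliberately written with plain Python loops and the
statistics stdlib module — no shared code with the package — so agreement
between the two routes is informative.
"""

import math
import statistics


def brute_force_scorecards(cohort, selection, plan, cutoff, rarity_bound=0.15):
    """Direct enumeration of criterion points and labels for every mouse.

    Recomputes transforms, control stats, exceedances and labels with plain
    loops; returns {mouse_id: (points_dict, total, label)}.
    """
    catalog = cohort.catalog
    rows = list(cohort.frame.to_dict(orient="records"))

    def transformed(row, name):
        v = row[name]
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        entry = plan.entries[name]
        if entry.transform == "log":
            return math.log(v + entry.offset)
        if entry.transform == "sqrt":
            return math.sqrt(v)
        return v

    # control stats per (sex, parameter)
    stats = {}
    sexes = sorted({r["sex"] for r in rows})
    for sex in sexes:
        for p in catalog.all_parameters:
            ctrl = [
                r for r in rows if r["sex"] == sex and r["group"] == "control"
            ]
            if p.kind == "continuous":
                vals = [transformed(r, p.name) for r in ctrl]
                vals = [v for v in vals if v is not None]
                stats[(sex, p.name)] = (
                    statistics.mean(vals),
                    statistics.stdev(vals),
                )
            else:
                outs = [r[p.name] for r in ctrl if isinstance(r[p.name], str)]
                stats[(sex, p.name)] = sum(o == "fail" for o in outs) / len(outs)

    out = {}
    for r in rows:
        sex = r["sex"]
        points = {}
        classifiable = True
        for crit in catalog.measurable_criteria:
            point = 0
            observed = False
            for name in selection.parameters_for(sex, crit):
                spec = catalog.get(name)
                if spec.kind == "continuous":
                    v = transformed(r, name)
                    if v is None:
                        continue
                    observed = True
                    mu, sd = stats[(sex, name)]
                    if abs((v - mu) / sd) > cutoff:
                        point = 1
                else:
                    o = r[name]
                    if not isinstance(o, str):
                        continue
                    observed = True
                    prev_fail = stats[(sex, name)]
                    prev = (
                        prev_fail
                        if spec.pathological_outcome == "fail"
                        else 1 - prev_fail
                    )
                    if o == spec.pathological_outcome and prev <= rarity_bound:
                        point = 1
            if not observed:
                classifiable = False
            points[crit] = point
        total = sum(points.values())
        full = len(catalog.measurable_criteria)
        if not classifiable:
            label = "unclassifiable"
        elif r["group"] == "control":
            label = "control_flagged" if total == full else "control"
        else:
            label = "susceptible" if total == full else "resilient"
        out[r["mouse_id"]] = (points, total, label)
    return out


def glass_delta_by_hand(exposed, control):
    return (statistics.mean(exposed) - statistics.mean(control)) / statistics.stdev(
        control
    )


def chi_square_by_hand(a, b, c, d):
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
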