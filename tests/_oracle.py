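"""Independent brute-force reference implementations.

Everything here recomputes decompositions and all 20 index values by raw
set enumeration only -- no count arithmetic shared with the package -- so
tests can treat it as an independent oracle. Deliberately slow and simple.
"""

from itertools import combinations
from math import log, log2


def oracle_decompose(net, x, y):
    """Classify every relevant incident link by raw set membership."""
    nx_, ny_ = set(net.neighbours(x)), set(net.neighbours(y))
    cn = (nx_ & ny_) - {x, y}
    ilcl = {i: sum(1 for j in net.neighbours(i) if j in cn) for i in cn}
    elcl = {
        i: sum(1 for j in net.neighbours(i) if j not in cn and j not in (x, y))
        for i in cn
    }
    nlcl_x = sum(1 for j in nx_ if j not in cn and j != y)
    nlcl_y = sum(1 for j in ny_ if j not in cn and j != x)
    lcl = sum(1 for i, j in combinations(sorted(cn), 2) if net.has_edge(i, j))
    return {
        "cn": cn,
        "ilcl": ilcl,
        "elcl": elcl,
        "nlcl_x": nlcl_x,
        "nlcl_y": nlcl_y,
        "lcl": lcl,
    }


def oracle_score(net, x, y, method, exponent=2):
    """Any of the 20 indices, recomputed from scratch by set enumeration."""
    nx_, ny_ = set(net.neighbours(x)), set(net.neighbours(y))
    cn = sorted((nx_ & ny_) - {x, y})
    union = nx_ | ny_
    deg = net.degree
    d = oracle_decompose(net, x, y)
    lcl = d["lcl"]
    car = len(cn) * lcl
    n_bar = 2 * net.n_edges / net.n_nodes

    if method == "CN":
        return len(cn)
    if method == "AA":
        return sum(1 / log(deg(i)) for i in cn)
    if method == "RA":
        return sum(1 / deg(i) for i in cn)
    if method == "PA":
        return deg(x) * deg(y)
    if method == "JC":
        return len(cn) / len(union) if cn else 0.0
    if method == "SCD":
        return 2 * len(cn) / (deg(x) + deg(y))
    if method == "LHN":
        return len(cn) / (deg(x) * deg(y))
    if method == "ACD":
        lam = lambda v: max(0.0, n_bar - deg(v))
        if not cn:
            return 0.0
        return 2 * len(cn) / (deg(x) + lam(x) + deg(y) + lam(y))
    if method == "FSW":
        sx, sy = nx_ | {x}, ny_ | {y}
        inter = len(sx & sy)
        if inter == 0:
            return 0.0
        lam_x = max(0.0, n_bar - (len(sx - sy) + 2 * inter))
        lam_y = max(0.0, n_bar - (len(sy - sx) + 2 * inter))
        return (2 * inter / (len(sx - sy) + 2 * inter + lam_x)) * (
            2 * inter / (len(sy - sx) + 2 * inter + lam_y)
        )
    if method == "IG1":
        return 1 + sum(1 for v in union - {x, y} if deg(v) == 1)
    if method == "LCL":
        return lcl
    if method == "CAR":
        return car
    if method == "CAA":
        return sum(d["ilcl"][i] / log2(deg(i)) for i in cn)
    if method == "CRA":
        return sum(d["ilcl"][i] / deg(i) for i in cn)
    if method == "CPA":
        ax, ay = d["nlcl_x"], d["nlcl_y"]
        return ax * ay + ax * car + ay * car + car * car
    if method == "CJC":
        return car / len(union) if car else 0.0
    if method == "C1":
        return sum(1 / (1 + d["elcl"][i]) for i in cn)
    if method == "C2":
        return sum(1 - 1 / (1 + d["ilcl"][i]) for i in cn)
    if method in ("C1star", "C2star"):
        raw = oracle_score(net, x, y, method[:2], exponent)
        if not cn:
            return 0.0
        denom = d["nlcl_x"] + d["nlcl_y"]
        return raw / (denom**exponent if denom else 1)
    raise ValueError(method)
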