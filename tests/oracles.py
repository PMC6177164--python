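"""Independent brute-force oracles used to cross-check the implementation.

Everything here deliberately avoids the code paths under test: covariances
come from explicit pairwise MRCA searches on node paths, GLS solutions from
explicit matrix inverses, and the lambda=1 slope from Felsenstein's
independent contrasts computed by pruning.
"""

import numpy as np


def vcv_bruteforce(tree):
    """n x n covariance from explicit root-paths and pairwise MRCA depths."""
    # path from root to each leaf as list of nodes
    paths = {}

    def walk(nd, path):
        path = path + [nd]
        if nd.is_leaf:
            paths[nd.name] = path
        for ch in nd.children:
            walk(ch, path)

    walk(tree.root, [])
    names = tree.tip_names

    def depth_of(node_path):
        return sum(nd.length or 0.0 for nd in node_path[1:])

    n = len(names)
    C = np.zeros((n, n))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            pa, pb = paths[a], paths[b]
            shared = 0
            while shared < min(len(pa), len(pb)) and pa[shared] is pb[shared]:
                shared += 1
            C[i, j] = depth_of(pa[:shared])
    return names, C


def gls_explicit(y, X, V):
    """Textbook GLS by explicit inversion: beta, se (n-p scale), t, sigma2_ml."""
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    e = y - X @ beta
    n, p = X.shape
    s2_resid = float(e @ Vi @ e) / (n - p)
    se = np.sqrt(np.diag(np.linalg.inv(XtViX)) * s2_resid)
    return beta, se, beta / se, float(e @ Vi @ e) / n


def contrasts_slope(tree, x, y):
    """Through-origin regression slope of Felsenstein independent contrasts.

    *x*, *y* are dicts keyed by tip name.  The tree must be strictly
    bifurcating.  Equals the PGLS slope at lambda = 1.
    """
    cx, cy = [], []

    def prune(nd):
        # returns (value_x, value_y, extra branch length at this node)
        if nd.is_leaf:
            return x[nd.name], y[nd.name], nd.length or 0.0
        assert len(nd.children) == 2, "contrasts oracle needs bifurcations"
        xa, ya, va = prune(nd.children[0])
        xb, yb, vb = prune(nd.children[1])
        w = np.sqrt(va + vb)
        cx.append((xa - xb) / w)
        cy.append((ya - yb) / w)
        xanc = (xa / va + xb / vb) / (1 / va + 1 / vb)
        yanc = (ya / va + yb / vb) / (1 / va + 1 / vb)
        extra = va * vb / (va + vb)
        return xanc, yanc, (nd.length or 0.0) + extra

    prune(tree.root)
    cx, cy = np.asarray(cx), np.asarray(cy)
    return float(cx @ cy / (cx @ cx))


def lilliefors_bruteforce(values):
    """D by enumerating both CDF gaps at every order statistic."""
    from scipy.stats import norm

    v = np.sort(np.asarray(values, float))
    n = len(v)
    mu, sd = v.mean(), v.std(ddof=1)
    best = 0.0
    for i, xi in enumerate(v, start=1):
        F = norm.cdf((xi - mu) / sd)
        best = max(best, abs(i / n - F), abs(F - (i - 1) / n))
    return best
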