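"""A-band cross-bridge census and myosin binding-preference analyses.

Covers the coordinate-level statistics of the rigor A-band: assignment
of fitted myosin heads to actin subunits and the occupancy against the
theoretical head budget (6 heads per 14.3 nm crown), double / single /
split topology, the R/G/B/E binding-profile encoding with a
custom-matrix multiple alignment (footprint hotspots), grouped circular
orientation statistics, and the bound-versus-free thin-to-thick distance
comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .errors import InputError, InsufficientDataError, ParameterError
from .helix import relative_orientation, wrap180, wrap360
from .model import SarcomereModel
from .specs import CROWN_SPACING_NM, HEADS_PER_CROWN
from .synth import theoretical_head_budget

logger = logging.getLogger(__name__)

PROFILE_ALPHABET = "RGBE"


# ---------------------------------------------------------------------------
# head assignment & occupancy
# ---------------------------------------------------------------------------

def occupancy_from_counts(n_assigned: int, n_theoretical: int) -> float:
    """Attached / theoretical head fraction (e.g. 2734 / 3315 = 82.5%)."""
    if n_theoretical <= 0:
        raise ParameterError("theoretical head count must be positive")
    return n_assigned / n_theoretical


def assign_heads(head_positions: pd.DataFrame, model: SarcomereModel,
                 capture_radius: float = 55.0) -> tuple[pd.DataFrame, dict]:
    """Assign head coordinates to their nearest actin subunit.

    ``head_positions`` needs columns x, y, z (Å) and origin_thick_id.
    Heads farther than ``capture_radius`` (default 55 Å, one subunit
    diameter) from any subunit are flagged unassigned (subunit_id = -1),
    never dropped.  The summary reports occupancy against the model's
    theoretical budget and the bound-subunit fraction.
    """
    if len(model.subunits) == 0:
        raise InputError("model has no subunits")
    tree = cKDTree(model.subunits[["x", "y", "z"]].to_numpy())
    pos = head_positions[["x", "y", "z"]].to_numpy(dtype=float)
    dist, idx = tree.query(pos)
    sub_ids = model.subunits.index.to_numpy()[idx]
    assigned = dist <= capture_radius
    out = head_positions.copy()
    out["subunit_id"] = np.where(assigned, sub_ids, -1)
    out["assign_distance"] = dist

    n_theory = model.meta.get("theoretical_heads")
    if n_theory is None:
        n_theory = sum(theoretical_head_budget(l / 10.0) for l in
                       model.filaments.loc[model.thick_ids(), "length"])
    n_assigned = int(assigned.sum())
    if (~assigned).any():
        logger.info("assign_heads: %d heads unassigned (no subunit within "
                    "%.0f Å)", int((~assigned).sum()), capture_radius)
    summary = dict(
        n_heads=len(out), n_assigned=n_assigned,
        n_unassigned=int((~assigned).sum()),
        n_theoretical=int(n_theory),
        occupancy=occupancy_from_counts(n_assigned, int(n_theory)) if n_theory else np.nan,
        bound_subunit_fraction=(out.loc[assigned, "subunit_id"].nunique()
                                / len(model.subunits)),
    )
    return out, summary


def classify_head_topology(heads: pd.DataFrame, model: SarcomereModel,
                           n_theoretical: int | None = None) -> dict:
    """Double / single / split census from myosin-id pairing.

    A myosin with two heads on the same thin filament is a double, on
    two different filaments a split; unpaired heads are singles.
    Fractions are reported against both the attached and (when known)
    theoretical head counts, since the published normalization is
    ambiguous.
    """
    if len(heads) == 0:
        return dict(n_double=0, n_single=0, n_split=0, n_heads=0,
                    frac=dict(), frac_theoretical=dict())
    sizes = heads.groupby("myosin_id").size()
    if (sizes > 2).any():
        raise InputError("a myosin_id carries more than 2 heads")
    fil_of = model.subunits["filament_id"]
    counts = dict(double=0, single=0, split=0)
    for mid, grp in heads.groupby("myosin_id"):
        subs = grp["subunit_id"].to_numpy()
        if len(grp) == 1 or (subs < 0).any():
            counts["single"] += len(grp[grp["subunit_id"] >= 0])
            continue
        fa, fb = fil_of.loc[subs[0]], fil_of.loc[subs[1]]
        counts["split" if fa != fb else "double"] += 2
    n = sum(counts.values())
    if n_theoretical is None:
        n_theoretical = model.meta.get("theoretical_heads")
    out = dict(n_double=counts["double"], n_single=counts["single"],
               n_split=counts["split"], n_heads=n,
               frac={k: v / n for k, v in counts.items()} if n else {})
    out["frac_theoretical"] = ({k: v / n_theoretical for k, v in counts.items()}
                               if n_theoretical else {})
    return out


# ---------------------------------------------------------------------------
# R/G/B/E profiles
# ---------------------------------------------------------------------------

@dataclass
class BindingProfile:
    filament_id: int
    strand: int                       # 1 or 2
    sequence: str                     # over R, G, B, E
    letter_of_thick: dict = field(default_factory=dict)


def encode_profiles(model: SarcomereModel, filament_id: int) -> list[BindingProfile]:
    """Encode one thin filament as two R/G/B/E strand sequences.

    The filament's three neighbour thick filaments get stable letters R,
    G, B in ascending id order; position i of strand s carries the
    binder's letter or E.  Filaments with fewer than three neighbours
    are encoded with the reduced alphabet and a warning.
    """
    nbrs = model.neighbors_of(filament_id)
    if len(nbrs) != 3:
        logger.warning("filament %s has %d neighbor thick filaments; "
                       "reduced alphabet", filament_id, len(nbrs))
    letter_of = {t: PROFILE_ALPHABET[i] for i, t in enumerate(sorted(nbrs))}
    subs = model.subunits[model.subunits["filament_id"] == filament_id]
    binder = {}
    if len(model.heads):
        hh = model.heads[model.heads["subunit_id"].isin(subs.index)]
        for _, h in hh.iterrows():
            binder[h["subunit_id"]] = letter_of.get(h["origin_thick_id"], "E")
    out = []
    for strand in (1, 2):
        ss = subs[subs["strand"] == strand - 1].sort_values("k")
        seq = "".join(binder.get(sid, "E") for sid in ss.index)
        out.append(BindingProfile(filament_id, strand, seq, letter_of))
    return out


@dataclass
class ProfileWeights:
    """Substitution scores over {R, G, B, E} with affine gaps.

    Defaults reward a conserved hotspot colour (+3), treat the abundant
    E background as weakly informative (E-E +1), and penalize colour
    clashes (-2) and colour-vs-E (-1); gap open -5, extend -1.
    """

    match: float = 3.0
    e_match: float = 1.0
    mismatch: float = -2.0
    color_vs_e: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0

    def score(self, a: str, b: str) -> float:
        if a == b:
            return self.e_match if a == "E" else self.match
        if "E" in (a, b):
            return self.color_vs_e
        return self.mismatch


def pairwise_align(seq_a: str, seq_b: str,
                   weights: ProfileWeights | None = None) -> tuple[str, str, float]:
    """Global alignment with affine gaps (Gotoh three-matrix recursion).

    Gap cost for a run of length L is ``gap_open + (L - 1) * gap_extend``.
    Returns the two gapped sequences and the optimal score.
    """
    w = weights or ProfileWeights()
    for s in (seq_a, seq_b):
        bad = set(s) - set(PROFILE_ALPHABET)
        if bad:
            raise InputError(f"sequence letters outside R/G/B/E alphabet: {bad}")
    n, m = len(seq_a), len(seq_b)
    NEG = -math.inf
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in seq_b (step in a)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in seq_a (step in b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = w.gap_open + (i - 1) * w.gap_extend
    for j in range(1, m + 1):
        Iy[0, j] = w.gap_open + (j - 1) * w.gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = w.score(seq_a[i - 1], seq_b[j - 1])
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(M[i - 1, j] + w.gap_open, Ix[i - 1, j] + w.gap_extend,
                           Iy[i - 1, j] + w.gap_open)
            Iy[i, j] = max(M[i, j - 1] + w.gap_open, Iy[i, j - 1] + w.gap_extend,
                           Ix[i, j - 1] + w.gap_open)
    score = max(M[n, m], Ix[n, m], Iy[n, m])

    # traceback
    out_a, out_b = [], []
    i, j = n, m
    state = max((("M", M[n, m]), ("Ix", Ix[n, m]), ("Iy", Iy[n, m])),
                key=lambda t: t[1])[0]
    tol = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            s = w.score(seq_a[i - 1], seq_b[j - 1])
            out_a.append(seq_a[i - 1])
            out_b.append(seq_b[j - 1])
            prev = M[i, j] - s
            i, j = i - 1, j - 1
            for st, val in (("M", M[i, j]), ("Ix", Ix[i, j]), ("Iy", Iy[i, j])):
                if abs(val - prev) < tol:
                    state = st
                    break
        elif state == "Ix":
            out_a.append(seq_a[i - 1])
            out_b.append("-")
            cur = Ix[i, j]
            i -= 1
            if abs(M[i, j] + w.gap_open - cur) < tol:
                state = "M"
            elif abs(Ix[i, j] + w.gap_extend - cur) < tol:
                state = "Ix"
            else:
                state = "Iy"
            if i == 0 and j == 0:
                break
        else:
            out_a.append("-")
            out_b.append(seq_b[j - 1])
            cur = Iy[i, j]
            j -= 1
            if abs(M[i, j] + w.gap_open - cur) < tol:
                state = "M"
            elif abs(Iy[i, j] + w.gap_extend - cur) < tol:
                state = "Iy"
            else:
                state = "Ix"
            if i == 0 and j == 0:
                break
        if i == 0 and j == 0:
            break
        if i == 0:
            state = "Iy"
        elif j == 0:
            state = "Ix"
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(score)


def _merge_into_msa(msa: list[str], center_aln: str, new_aln: str) -> list[str]:
    """Merge a (center, new) pairwise alignment into an existing MSA whose
    first row is the center ('once a gap, always a gap')."""
    merged_old: list[list[str]] = [[] for _ in msa]
    merged_new: list[str] = []
    ci = 0  # column in existing msa
    for a, b in zip(center_aln, new_aln):
        if a == "-":
            for row in merged_old:
                row.append("-")
            merged_new.append(b)
        else:
            # advance past any all-center-gap columns already in the MSA
            while ci < len(msa[0]) and msa[0][ci] == "-":
                for r, row in enumerate(merged_old):
                    row.append(msa[r][ci])
                merged_new.append("-")
                ci += 1
            for r, row in enumerate(merged_old):
                row.append(msa[r][ci])
            merged_new.append(b)
            ci += 1
    while ci < len(msa[0]):
        for r, row in enumerate(merged_old):
            row.append(msa[r][ci])
        merged_new.append("-")
        ci += 1
    return ["".join(r) for r in merged_old] + ["".join(merged_new)]


def align_profiles(sequences: list[str],
                   weights: ProfileWeights | None = None) -> dict:
    """Center-star progressive multiple alignment of R/G/B/E profiles.

    The center is the sequence maximizing the summed pairwise score
    (ties by input order); every other sequence is merged through its
    pairwise alignment to the center.  Returns the MSA (rows in input
    order), the center index, and column-wise occurrence counts per
    letter — the myosin-binding footprint.
    """
    w = weights or ProfileWeights()
    if len(sequences) < 2:
        raise InputError("need at least two sequences")
    n = len(sequences)
    scores = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, s = pairwise_align(sequences[i], sequences[j], w)
            scores[i, j] = scores[j, i] = s
    center = int(np.argmax(scores.sum(axis=1)))

    msa = [sequences[center]]
    order = [center]
    for j in range(n):
        if j == center:
            continue
        ca, ja, _ = pairwise_align("".join(c for c in msa[0] if c != "-"),
                                   sequences[j], w)
        msa = _merge_into_msa(msa, ca, ja)
        order.append(j)
    # restore input order
    rows = [None] * n
    for row, j in zip(msa, order):
        rows[j] = row
    width = len(rows[0])
    counts = pd.DataFrame(0, index=range(width),
                          columns=list(PROFILE_ALPHABET) + ["-"])
    for row in rows:
        for pos, ch in enumerate(row):
            counts.loc[pos, ch] += 1
    return dict(msa=rows, center_index=center, counts=counts,
                pairwise_scores=scores)


def map_strand2(msa_row: str, strand2_seq: str) -> str:
    """Project a strand-2 sequence through its filament's strand-1 alignment.

    Gap columns of the aligned strand-1 row are copied as gaps; letter
    columns consume strand-2 letters in order (padded with E when strand
    2 is one subunit shorter).
    """
    out = []
    i = 0
    for ch in msa_row:
        if ch == "-":
            out.append("-")
        else:
            out.append(strand2_seq[i] if i < len(strand2_seq) else "E")
            i += 1
    return "".join(out)


# ---------------------------------------------------------------------------
# angular statistics
# ---------------------------------------------------------------------------

def bound_orientations(model: SarcomereModel) -> pd.DataFrame:
    """Relative orientation of every bound subunit toward its binder.

    Returns a table with the wrapped azimuth-minus-bearing angle, the
    origin thick filament and its R/G/B role in the thin filament's
    neighbour triple.
    """
    rows = []
    fil = model.filaments
    for _, h in model.heads.iterrows():
        sid = h["subunit_id"]
        if sid < 0:
            continue
        s = model.subunits.loc[sid]
        thin_id = s["filament_id"]
        nbrs = sorted(model.neighbors_of(thin_id))
        t = h["origin_thick_id"]
        role = PROFILE_ALPHABET[nbrs.index(t)] if t in nbrs else "?"
        thin_pt = model.filament_axis_point(thin_id, s["y"])
        thick_pt = model.filament_axis_point(t, s["y"])
        rel = float(relative_orientation(s["azimuth"], thin_pt, thick_pt))
        rows.append(dict(subunit_id=sid, thin_id=thin_id, thick_id=t,
                         group=role, rel_orientation=rel,
                         azimuth=s["azimuth"]))
    return pd.DataFrame(rows)


def angular_span(angles_deg: np.ndarray, mass: float = 1.0) -> float:
    """Minimal arc (deg) containing the given fraction of the samples."""
    a = np.sort(wrap360(np.asarray(angles_deg, dtype=float)))
    n = len(a)
    if n == 0:
        raise InsufficientDataError("no angles")
    if n == 1:
        return 0.0
    if mass >= 1.0:
        gaps = np.diff(np.concatenate([a, [a[0] + 360.0]]))
        return float(360.0 - gaps.max())
    k = max(1, int(math.ceil(mass * n)))
    ext = np.concatenate([a, a + 360.0])
    spans = ext[k - 1: k - 1 + n] - a
    return float(spans.min())


def circular_mean_deg(angles_deg: np.ndarray) -> float:
    z = np.exp(1j * np.radians(np.asarray(angles_deg, dtype=float)))
    return float(np.degrees(np.angle(z.mean())))


def angular_distribution(angles_deg, groups, bin_width: float = 10.0,
                         mass: float = 1.0) -> dict:
    """Per-group circular histograms, means and minimal-arc spans.

    Empty groups are skipped with a warning.  Bin edges tile [0, 360)
    with the given width.
    """
    if 360.0 % bin_width:
        raise ParameterError("bin_width must divide 360")
    angles_deg = np.asarray(angles_deg, dtype=float)
    groups = np.asarray(groups)
    edges = np.arange(0.0, 360.0 + bin_width, bin_width)
    out = {}
    for g in pd.unique(groups):
        vals = wrap360(angles_deg[groups == g])
        if len(vals) == 0:
            logger.warning("angular_distribution: empty group %r skipped", g)
            continue
        hist, _ = np.histogram(vals, bins=edges)
        out[g] = dict(n=len(vals), histogram=hist, bin_edges=edges,
                      circular_mean=circular_mean_deg(vals),
                      span=angular_span(vals, mass))
    return out


# ---------------------------------------------------------------------------
# distance statistics
# ---------------------------------------------------------------------------

def measure_thin_thick_distances(model: SarcomereModel) -> tuple[np.ndarray, np.ndarray]:
    """Thin-to-thick axis distances (nm) split into bound / free populations.

    Every subunit contributes exactly three measurements, one per
    neighbour thick filament: an unbound subunit gives 3 free distances;
    a bound subunit gives 1 bound distance (to its binder) and 2 free.
    """
    fil = model.filaments
    binder = {}
    for _, h in model.heads.iterrows():
        if h["subunit_id"] >= 0:
            binder[h["subunit_id"]] = h["origin_thick_id"]
    bound, free = [], []
    for thin_id in model.thin_ids():
        nbrs = model.neighbors_of(thin_id)
        fx, fz = fil.loc[thin_id, ["x", "z"]]
        dists = {t: math.hypot(fil.loc[t, "x"] - fx, fil.loc[t, "z"] - fz) / 10.0
                 for t in nbrs}
        subs = model.subunits[model.subunits["filament_id"] == thin_id]
        for sid in subs.index:
            bt = binder.get(sid)
            for t in nbrs:
                (bound if t == bt else free).append(dists[t])
    return np.asarray(bound), np.asarray(free)


def _skewness_test(x: np.ndarray) -> dict:
    n = len(x)
    if n < 3 or float(np.std(x)) <= 1e-9 * max(abs(float(np.mean(x))), 1.0):
        return dict(skewness=0.0, se=np.nan, z=0.0, p=1.0, significant=False)
    g1 = float(stats.skew(x, bias=False))
    se = math.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3)))
    z = g1 / se
    p = 2.0 * (1.0 - stats.norm.cdf(abs(z)))
    return dict(skewness=g1, se=se, z=z, p=p, significant=abs(z) > 1.96)


def distance_statistics(bound: np.ndarray, free: np.ndarray,
                        ci_method: str = "welch", n_boot: int = 10000,
                        seed: int = 0, alpha: float = 0.05) -> dict:
    """Bound / free distance summaries and the difference of means.

    Reports mean, SD and a sample-skewness normality check per
    population, and the free-minus-bound difference of means with a 95%
    CI (Welch normal approximation by default; seeded percentile
    bootstrap with ``ci_method='bootstrap'``).
    """
    bound = np.asarray(bound, dtype=float)
    free = np.asarray(free, dtype=float)
    if len(bound) < 2 or len(free) < 2:
        raise InsufficientDataError("need >= 2 samples in each population")
    res = {}
    for name, x in (("bound", bound), ("free", free)):
        res[name] = dict(n=len(x), mean=float(x.mean()),
                         sd=float(x.std(ddof=1)), **_skewness_test(x))
    diff = res["free"]["mean"] - res["bound"]["mean"]
    if ci_method == "welch":
        se = math.sqrt(res["bound"]["sd"] ** 2 / len(bound)
                       + res["free"]["sd"] ** 2 / len(free))
        zc = stats.norm.ppf(1.0 - alpha / 2.0)
        ci = (diff - zc * se, diff + zc * se)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            reps[b] = (rng.choice(free, len(free)).mean()
                       - rng.choice(bound, len(bound)).mean())
        ci = (float(np.quantile(reps, alpha / 2)),
              float(np.quantile(reps, 1 - alpha / 2)))
    else:
        raise ParameterError("ci_method must be 'welch' or 'bootstrap'")
    res["difference"] = dict(mean=float(diff), ci=tuple(map(float, ci)),
                             method=ci_method)
    return res
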