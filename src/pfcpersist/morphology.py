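"""Neuronal morphology: SWC I/O, a surrogate layer-V pyramidal cell generator,
and path-distance computations.

A morphology is a tree of cylindrical sections, each tagged with a region
(soma, axon, basal or apical dendrite).  The surrogate generator emulates a
rat layer-V prefrontal pyramidal reconstruction at the section level: 45
sections (1 soma, 1 axon, 18 basal, 25 apical) with basal branch centres
spanning roughly 15-110 um path distance from the soma, and total membrane
area scaled so that the passive somatic input resistance hits a target value
(81 MOhm by default, the physiological average for these cells).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

REGIONS = ("soma", "axon", "basal", "apical")
_SWC_TYPE = {1: "soma", 2: "axon", 3: "basal", 4: "apical"}
_SWC_CODE = {v: k for k, v in _SWC_TYPE.items()}

DEFAULT_COUNTS = {"soma": 1, "axon": 1, "basal": 18, "apical": 25}


class SWCParseError(ValueError):
    """Malformed SWC content."""


class SWCStructureError(ValueError):
    """Topologically invalid SWC content (bad parents, missing soma)."""


class MorphologyError(ValueError):
    """Invalid morphology or lookup failure."""


class CalibrationError(RuntimeError):
    """Input-resistance target unreachable within admissible geometry bounds."""

    def __init__(self, msg: str, achieved: float):
        super().__init__(msg)
        self.achieved = achieved


@dataclass(frozen=True)
class Section:
    """One unbranched cylindrical cable section.

    Children attach to the distal (position 1.0) end of their parent;
    positions along a section are normalised to [0, 1] with 0 at the
    parent end.
    """

    id: int
    region: str
    parent_id: int | None
    length: float  # um
    diameter: float  # um

    def __post_init__(self):
        if self.region not in REGIONS:
            raise MorphologyError(f"unknown region {self.region!r}")
        if not self.length > 0:
            raise MorphologyError(f"section {self.id}: length must be > 0")
        if not self.diameter > 0:
            raise MorphologyError(f"section {self.id}: diameter must be > 0")

    @property
    def area(self) -> float:
        """Lateral membrane area in um^2."""
        return math.pi * self.diameter * self.length


@dataclass(frozen=True)
class BranchLocation:
    """A point on a section, as a normalised position in [0, 1]."""

    section_id: int
    position: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.position <= 1.0:
            raise MorphologyError(
                f"position {self.position} outside [0, 1] on section {self.section_id}"
            )


@dataclass
class Morphology:
    """An ordered, rooted tree of sections (the root is the soma)."""

    sections: list[Section] = field(default_factory=list)

    def __post_init__(self):
        self._index = {s.id: i for i, s in enumerate(self.sections)}
        if len(self._index) != len(self.sections):
            raise MorphologyError("duplicate section ids")
        roots = [s for s in self.sections if s.parent_id is None]
        if len(roots) != 1 or roots[0].region != "soma":
            raise MorphologyError("exactly one root section (the soma) is required")
        seen = set()
        for s in self.sections:
            if s.parent_id is not None and s.parent_id not in seen:
                raise MorphologyError(
                    f"section {s.id}: parent {s.parent_id} not defined before child"
                )
            seen.add(s.id)

    def __len__(self) -> int:
        return len(self.sections)

    def section(self, section_id: int) -> Section:
        try:
            return self.sections[self._index[section_id]]
        except KeyError:
            raise MorphologyError(f"unknown section id {section_id}") from None

    @property
    def soma(self) -> Section:
        return next(s for s in self.sections if s.parent_id is None)

    @property
    def counts_by_region(self) -> dict[str, int]:
        out = {r: 0 for r in REGIONS}
        for s in self.sections:
            out[s.region] += 1
        return out

    def children(self, section_id: int) -> list[Section]:
        return [s for s in self.sections if s.parent_id == section_id]

    def basal_sections(self) -> list[Section]:
        return [s for s in self.sections if s.region == "basal"]

    def total_area(self) -> float:
        """Total membrane area in um^2."""
        return sum(s.area for s in self.sections)

    def path_distance(self, loc: BranchLocation) -> float:
        """Path distance (um) from the soma centre to ``loc``.

        The soma is treated as a point origin: its own length does not
        contribute, so any location on the soma is at distance 0.
        """
        sec = self.section(loc.section_id)
        if sec.region == "soma":
            return 0.0
        d = loc.position * sec.length
        while sec.parent_id is not None:
            parent = self.section(sec.parent_id)
            if parent.parent_id is None:  # reached the soma
                break
            d += parent.length
            sec = parent
        return d

    def branch_center_distance(self, section_id: int) -> float:
        return self.path_distance(BranchLocation(section_id, 0.5))


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def load_swc(path) -> Morphology:
    """Read a standard 7-column SWC reconstruction into a Morphology.

    Chains of same-type points with single children are merged into one
    section; sections start at the soma, at branch points, and at type
    changes.  Section length is the summed 3-D distance between consecutive
    points (including the edge from the parent point), and diameter is twice
    the mean point radius.  The soma contour is collapsed into a single
    cylinder with matching membrane area.
    """
    pts: dict[int, tuple] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 7:
                raise SWCParseError(f"line {lineno}: expected 7 columns, got {len(cols)}")
            try:
                pid = int(cols[0])
                ptype = int(cols[1])
                x, y, z, r = (float(c) for c in cols[2:6])
                parent = int(cols[6])
            except ValueError as e:
                raise SWCParseError(f"line {lineno}: {e}") from None
            if pid in pts:
                raise SWCParseError(f"line {lineno}: duplicate point id {pid}")
            if parent != -1 and parent not in pts:
                raise SWCStructureError(
                    f"line {lineno}: point {pid} references undefined parent {parent}"
                )
            if ptype not in _SWC_TYPE:
                raise SWCParseError(f"line {lineno}: unsupported SWC type {ptype}")
            pts[pid] = (ptype, np.array([x, y, z]), r, parent)

    soma_ids = [i for i, p in pts.items() if p[0] == 1]
    if not soma_ids:
        raise SWCStructureError("no soma point in file")

    children: dict[int, list[int]] = {i: [] for i in pts}
    for i, p in pts.items():
        if p[3] != -1:
            children[p[3]].append(i)

    # Soma: one cylinder, area-matched to the contour (sum of point "disks"
    # approximated by a cylinder of mean diameter and total path length; for
    # a single-point soma use the L = D = 2r convention).
    mean_r = float(np.mean([pts[i][2] for i in soma_ids]))
    soma_len = 0.0
    for i in soma_ids:
        parent = pts[i][3]
        if parent in soma_ids:
            soma_len += float(np.linalg.norm(pts[i][1] - pts[parent][1]))
    if soma_len <= 0:
        soma_len = 2 * mean_r

    sections: list[Section] = [
        Section(id=0, region="soma", parent_id=None, length=soma_len, diameter=2 * mean_r)
    ]
    point_section: dict[int, int] = {i: 0 for i in soma_ids}
    next_id = 1

    # Walk non-soma points depth-first from soma attachments, merging runs.
    def neurite_starts():
        for i in sorted(pts):
            ptype, _, _, parent = pts[i]
            if ptype == 1:
                continue
            if parent == -1 or pts[parent][0] == 1 or pts[parent][0] != ptype:
                yield i

    stack = sorted(neurite_starts(), reverse=True)
    while stack:
        start = stack.pop()
        ptype = pts[start][0]
        run = [start]
        while True:
            kids = [k for k in children[run[-1]] if pts[k][0] == ptype]
            other = [k for k in children[run[-1]] if pts[k][0] != ptype]
            stack.extend(sorted(other, reverse=True))
            if len(kids) == 1:
                run.append(kids[0])
            else:
                stack.extend(sorted(kids, reverse=True))
                break
        length = 0.0
        prev = pts[start][3]
        for i in run:
            if prev != -1:
                length += float(np.linalg.norm(pts[i][1] - pts[prev][1]))
            prev = i
        diam = 2 * float(np.mean([pts[i][2] for i in run]))
        if length <= 0:
            length = max(diam, 1e-3)
        parent_pt = pts[start][3]
        parent_sec = 0 if parent_pt == -1 else point_section[parent_pt]
        sections.append(
            Section(
                id=next_id,
                region=_SWC_TYPE[ptype],
                parent_id=parent_sec,
                length=length,
                diameter=diam,
            )
        )
        for i in run:
            point_section[i] = next_id
        next_id += 1

    return Morphology(sections)


def write_swc(m: Morphology, path) -> None:
    """Write a morphology as single-point-per-section SWC.

    3-D coordinates are synthetic (sections are laid out on deterministic
    rays); topology, region tags, lengths and diameters round-trip through
    :func:`load_swc` within floating tolerance.
    """
    coords: dict[int, np.ndarray] = {}
    lines = []
    golden = math.pi * (3.0 - math.sqrt(5.0))
    point_of_section: dict[int, int] = {}
    for n, s in enumerate(m.sections, start=1):
        if s.parent_id is None:
            coords[s.id] = np.zeros(3)
            lines.append(f"1 1 0.0 0.0 0.0 {s.diameter / 2:.9f} -1")
            point_of_section[s.id] = 1
            continue
        theta = golden * s.id
        zdir = math.cos(0.5 + 0.13 * s.id)
        rho = math.sqrt(max(1e-9, 1 - zdir * zdir))
        direction = np.array([rho * math.cos(theta), rho * math.sin(theta), zdir])
        origin = coords[s.parent_id]
        end = origin + direction * s.length
        coords[s.id] = end
        lines.append(
            f"{n} {_SWC_CODE[s.region]} {end[0]:.9f} {end[1]:.9f} {end[2]:.9f} "
            f"{s.diameter / 2:.9f} {point_of_section[s.parent_id]}"
        )
        point_of_section[s.id] = n
    with open(path, "w") as fh:
        fh.write("# generated by pfcpersist\n")
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Passive input resistance (steady-state cable solve)
# ---------------------------------------------------------------------------

def passive_input_resistance(
    m: Morphology,
    rm_kohm_cm2: float = 30.0,
    ra_ohm_cm: float = 100.0,
    seg_um: float = 5.0,
) -> float:
    """Steady-state somatic input resistance (MOhm) of the passive cell.

    Solves G v = i on a fine uniform discretisation (segments of at most
    ``seg_um``) with leak conductance 1/Rm everywhere; returns the soma
    diagonal of the inverse, i.e. delta-V per unit injected current.
    """
    comp_parent: list[int] = []
    comp_g_leak: list[float] = []  # uS
    comp_g_ax: list[float] = []  # uS, coupling to parent
    sec_last: dict[int, int] = {}

    for s in m.sections:
        nseg = max(1, int(math.ceil(s.length / seg_um)))
        lseg = s.length / nseg  # um
        area_cm2 = math.pi * s.diameter * lseg * 1e-8
        g_leak = area_cm2 / (rm_kohm_cm2 * 1e3) * 1e6  # S -> uS
        # axial resistance of one half segment, MOhm
        r_half = ra_ohm_cm * (lseg * 1e-4 / 2) / (math.pi * (s.diameter * 1e-4 / 2) ** 2) * 1e-6
        for k in range(nseg):
            idx = len(comp_parent)
            if k == 0:
                if s.parent_id is None:
                    comp_parent.append(-1)
                    comp_g_ax.append(0.0)
                else:
                    pidx = sec_last[s.parent_id]
                    psec = m.section(s.parent_id)
                    pn = max(1, int(math.ceil(psec.length / seg_um)))
                    pl = psec.length / pn
                    pr_half = (
                        ra_ohm_cm * (pl * 1e-4 / 2)
                        / (math.pi * (psec.diameter * 1e-4 / 2) ** 2)
                        * 1e-6
                    )
                    comp_parent.append(pidx)
                    comp_g_ax.append(1.0 / (r_half + pr_half))
            else:
                comp_parent.append(idx - 1)
                comp_g_ax.append(1.0 / (2 * r_half))
            comp_g_leak.append(g_leak)
        sec_last[s.id] = len(comp_parent) - 1

    n = len(comp_parent)
    rows, cols, vals = [], [], []
    diag = np.array(comp_g_leak, dtype=float)
    for i in range(n):
        p = comp_parent[i]
        if p >= 0:
            g = comp_g_ax[i]
            diag[i] += g
            diag[p] += g
            rows += [i, p]
            cols += [p, i]
            vals += [-g, -g]
    rows += list(range(n))
    cols += list(range(n))
    vals += list(diag)
    G = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
    i_vec = np.zeros(n)
    i_vec[0] = 1.0  # 1 nA at the soma
    v = spla.spsolve(G, i_vec)  # uS^-1 * nA = mV; mV/nA = MOhm... (1 nA / 1 uS = 1 mV)
    return float(v[0])  # MOhm


# ---------------------------------------------------------------------------
# Surrogate morphology
# ---------------------------------------------------------------------------

def make_surrogate_morphology(
    seed: int = 1,
    counts: dict[str, int] | None = None,
    target_rin: float = 81.0,
    rm_kohm_cm2: float = 30.0,
    ra_ohm_cm: float = 100.0,
) -> Morphology:
    """Generate a surrogate layer-V pyramidal morphology.

    The basal tree is arranged as up to 8 primary trunks (30-60 um, ~2 um
    diameter) carrying daughter branches (40-100 um, tapering to ~1 um), so
    branch-centre path distances span a proximal-to-distal range; the apical
    tree is a tapering trunk with oblique branches and acts mostly as a
    capacitive/resistive load.  Apical diameters are scaled by a single
    factor (bisection, bounds 0.25-4.0) until the passive input resistance
    matches ``target_rin`` within 0.1%.

    Deterministic for a given (seed, counts, target_rin).
    """
    counts = dict(DEFAULT_COUNTS if counts is None else counts)
    for r in REGIONS:
        counts.setdefault(r, 0)
    if counts["soma"] != 1:
        raise MorphologyError("exactly one soma section is required")
    if target_rin <= 0:
        raise MorphologyError("target_rin must be > 0")

    rng = np.random.default_rng(seed)
    sections: list[Section] = [Section(0, "soma", None, 20.0, 20.0)]
    nid = 1

    if counts["axon"]:
        for _ in range(counts["axon"]):
            sections.append(Section(nid, "axon", 0, 60.0, 1.2))
            nid += 1

    # Basal: primaries off the soma, daughters added in sibling groups of >= 2
    # so the tree contains no unbranched same-type junctions (these would not
    # survive an SWC round trip).
    n_basal = counts["basal"]
    n_primary = min(8, n_basal)
    n_daughters = n_basal - n_primary
    primary_ids = []
    for _ in range(n_primary):
        L = float(rng.uniform(30.0, 60.0))
        d = float(rng.uniform(1.7, 2.1))
        sections.append(Section(nid, "basal", 0, L, d))
        primary_ids.append(nid)
        nid += 1
    group_sizes = [2] * (n_daughters // 2)
    if n_daughters % 2:
        if group_sizes:
            group_sizes[0] = 3
        else:
            group_sizes = [n_daughters]  # degenerate tiny trees
    hosts = list(rng.permutation(primary_ids))[: len(group_sizes)]
    for host, size in zip(hosts, group_sizes):
        for _ in range(size):
            L = float(rng.uniform(40.0, 100.0))
            d = float(rng.uniform(0.8, 1.2))
            sections.append(Section(nid, "basal", int(host), L, d))
            nid += 1

    # Apical: trunk chain plus obliques; every trunk junction carries at
    # least one oblique and the terminal trunk carries none or >= 2.
    n_apical = counts["apical"]
    n_trunk = min(5, n_apical)
    n_obl = n_apical - n_trunk
    trunk_ids = []
    parent = 0
    for t in range(n_trunk):
        L = float(rng.uniform(120.0, 180.0))
        d = float(np.interp(t, [0, max(1, n_trunk - 1)], [4.0, 2.0]))
        sections.append(Section(nid, "apical", parent, L, d))
        trunk_ids.append(nid)
        parent = nid
        nid += 1
    per_host = {h: 0 for h in trunk_ids}
    if n_trunk > 1 and n_obl:
        need = trunk_ids[:-1]  # junction hosts
        extra = n_obl - len(need)
        if extra < 0:
            raise MorphologyError("apical count too small for the trunk layout")
        for h in need:
            per_host[h] += 1
        last = trunk_ids[-1]
        if extra == 1:
            per_host[trunk_ids[0]] += 1
        elif extra >= 2:
            take_last = int(rng.integers(2, extra + 1)) if extra > 2 else 2
            per_host[last] += take_last
            for _ in range(extra - take_last):
                per_host[int(rng.choice(trunk_ids[:-1]))] += 1
    elif n_obl:
        per_host[trunk_ids[0]] = n_obl
    for host in trunk_ids:
        for _ in range(per_host[host]):
            L = float(rng.uniform(80.0, 160.0))
            d = float(rng.uniform(1.0, 1.6))
            sections.append(Section(nid, "apical", host, L, d))
            nid += 1

    base = Morphology(sections)

    has_apical = counts["apical"] > 0

    def scaled(factor: float) -> Morphology:
        # the apical tree is the adjustable load; for apical-free test
        # geometries fall back to scaling the basal diameters
        region = "apical" if has_apical else "basal"
        out = []
        for s in base.sections:
            if s.region == region:
                out.append(replace(s, diameter=s.diameter * factor))
            else:
                out.append(s)
        return Morphology(out)

    def rin(factor: float) -> float:
        return passive_input_resistance(scaled(factor), rm_kohm_cm2, ra_ohm_cm)

    lo, hi = 0.25, 4.0
    r_lo, r_hi = rin(lo), rin(hi)  # Rin decreases with diameter
    if not (r_hi <= target_rin <= r_lo):
        achieved = min((r_lo, r_hi), key=lambda r: abs(r - target_rin))
        raise CalibrationError(
            f"target Rin {target_rin} MOhm unreachable within diameter bounds "
            f"(achievable range [{r_hi:.1f}, {r_lo:.1f}] MOhm)",
            achieved=achieved,
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        r_mid = rin(mid)
        if abs(r_mid - target_rin) / target_rin < 1e-3:
            break
        if r_mid > target_rin:
            lo = mid
        else:
            hi = mid
    return scaled(mid)
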