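# Methods

## The model

`strainseg` segments a 2D CT slice by simulating its mechanical
destruction. The working assumption is anatomical: the interference
region between two dense regions (the cartilage between two bones, the
septum between orange segments) is structurally weak, so under a
suitable external load it carries the highest strain and is where the
object would physically break. Segmenting along that break line is
exactly the cut a human annotator wants.

### Pixel-based finite elements

Every foreground pixel — intensity at or above a global threshold —
becomes one plane-stress bilinear quadrilateral element occupying the
unit square `[i, i+1] x [j, j+1]`; pixel corners are the nodes. Because
all elements are congruent unit squares, the 8x8 element stiffness is a
single matrix `k(nu)` scaled by the element's Young's modulus, and is
integrated exactly by 2x2 Gauss quadrature (verified against symbolic
integration in the test suite).

The modulus follows a cube law in intensity, `E = E0 (v / v_max)^3`,
the standard density–stiffness relation for bone with CT intensity as
the density proxy. Normalizing by the maximum foreground intensity
makes the model invariant to global intensity rescaling, and only
relative strain matters for segmentation, so `E0 = 1` by default.
Poisson's ratio is a single constant, default 0.3 (bone-like solid);
plane stress is the default reading of a thin slice, with plane strain
available.

### Weak-spring regularization

The assembled stiffness `K` is singular (rigid-body modes) and picking
support nodes on an arbitrary anatomy is itself a hard problem, so a
weak spring to ground is attached to every dof: `K_reg = K + c I`.
The coefficient matters more than it first appears. A joint-like
structure has a nearly floppy mode — two stiff regions hinging about
the soft neck — whose stiffness eigenvalue can be as small as ~1e-9 of
the largest diagonal entry on large rasters. If `c` competes with that
mode, the springs visibly damp exactly the deformation the method
relies on. The default `spring_factor = 1e-11` (times `max diag K`)
was chosen from that eigenvalue analysis: far below every elastic mode
of the geometries this tool targets, far above zero. The test suite
verifies that multiplying `c` by 10 changes ROI strain sums by well
under 1%.

The price is conditioning (~1/spring_factor). The direct solver
(SuperLU) therefore runs a few steps of iterative refinement, and the
solve contract is backward-stable: `||K_reg u - f|| <= rtol (||f|| +
||K_reg|| ||u||)` with `rtol = 1e-8`. A residual measured against
`||f||` alone is unattainable in double precision when an unbalanced
load rides on springs this soft. Above 400k dofs the factorization is
replaced by diagonally preconditioned conjugate gradients.

### Strain and its scalar summary

Strain is evaluated once per element at the center, `eps = B(0,0) u_e`,
giving one `(eps_x, eps_y, gamma_xy)` triple per pixel. Elements are
ranked by the von Mises equivalent strain

    eps_vM = sqrt(eps_x^2 + eps_y^2 - eps_x eps_y + (3/4) gamma_xy^2),

which is non-negative, invariant under in-plane rotation and
positively homogeneous of degree 1 — the three properties the
algorithm actually uses. The deviatoric variant (constant factor 2/3)
is available; it rescales every value identically and cannot change a
segmentation.

### Load optimization

External forces live on boundary nodes only (nodes touching an exposed
pixel edge) and act along outward surface normals (per-node normal =
normalized sum of its exposed edge normals), so the load is a scalar
magnitude per boundary node. Boundary nodes within a 1-pixel dilation
of the ROI are excluded: loading inside the region to be cut would
trivially self-strain it. The objective

    Phi(f) = sum over ROI elements of eps_vM

is degree-1 homogeneous in the load, so the problem is only well posed
on the unit sphere `||f|| = 1`. Optimization is projected gradient
ascent on that sphere with Armijo backtracking (sufficient-increase
1e-4, backtrack 1/2, textbook values), stopping at relative
improvement < 1e-6 or 200 iterations. The initial guess pushes each
boundary node away from the intensity-weighted centroid — pulling the
two regions apart.

The gradient is computed analytically with one adjoint solve:
`dPhi/du` assembles per ROI element as `B^T M eps / eps_vM` (`M` the
von Mises quadratic form; elements with numerically zero strain get
the valid zero subgradient), is pulled back through the symmetric
`K_reg`, and contracted with the node normals. Two numerical details:
`dPhi/du` is exactly orthogonal to the rigid-body modes (rigid motion
is strain-free), and so is the exact adjoint, so both are projected
onto the rigid-free complement — otherwise the factorization
reintroduces rounding-level rigid content amplified by `1/c`. The
gradient is certified against central finite differences (step 1e-3,
chosen so FD truncation and the conditioning-limited solver noise are
both well below the 1e-4 certification level) and against the Euler
identity `<grad Phi, s> = Phi`.

### Destruction and repair

With the optimized load fixed, the loop alternates: reassemble the
system on the current foreground of the ROI's connected component,
re-apply the load (magnitudes are keyed by lattice position; entries
whose nodes vanished are dropped and the load renormalized), solve,
and remove the single ROI pixel with the highest von Mises strain.
Removal is restricted to the ROI — the load application points must
not be eaten away — and one pixel per iteration keeps the halting
check exact. The loop halts when the component's 4-connected component
count increases; failing to decompose within `2 x ROI area` removals
is an error carrying the partial state. The load is not re-optimized
during destruction.

Repair then salvages the removed pixels: surviving components are
labeled 1..k (largest first, scan-order ties), and the labels grow
back simultaneously over the removed set by multi-source BFS
(4-connected, restricted to removed pixels; simultaneous rounds, ties
to the lower label). A removed pixel no front reaches is attached to
the component with the nearest centroid. Every original foreground
pixel ends up labeled — conservation is asserted in the pipeline.

### Multiple ROIs and doubtful ROIs

Each ROI gets its own optimized load on the pristine foreground;
ROIs are then ranked by structural weakness `Phi* / area`. An ROI
whose weakness falls below `0.1 x` the maximum is doubtful — a user
mistook solid material for a joint — and is skipped rather than
force-broken (on the decoy phantom the ratio comes out near 0.003, so
the 0.1 threshold is not delicate). Destruction runs per ROI in
weakness order on the evolving foreground; components not containing
the current ROI are frozen.

## The phantom generator

Phantoms emulate the geometry the method targets: dense blocks
(intensity 200) joined by thin, fainter necks (intensity 60, the
interference region), thresholded at 50 — a conservative threshold
well below the faintest structure, as one would choose on real CT.
The cube law makes the neck ~27x softer than the blocks. Kinds:
`dumbbell` (2 blocks, 1 neck), `chain` (3 blocks, 2 necks),
`decoy_chain` (chain plus an ROI over solid block interior),
`knee_like` (two round condyle-like blobs bridged by a soft band).
ROI masks cover each neck with a 2-pixel margin; ground-truth labels
split each neck at its midline.

Noise is Gaussian on structure pixels (default sigma 0; the noisy test
condition uses sigma = 10, i.e. 5% of block intensity), truncated
below at threshold+1 and clipped at 0. The truncation is deliberate:
untruncated noise at that sigma would stochastically flip neck pixels
below threshold and background pixels above it, changing the topology
of the test object rather than its intensities, and a generator whose
ground truth is only probabilistically correct cannot anchor a test.
What the phantoms do not emulate: beam hardening, partial-volume
blur, correlated noise, curved anatomy at real resolutions — so
passing tests show the algorithm is correct on its own model of the
problem, not that it is robust to every CT artifact.

## Numerical choices and degenerate inputs

- Argmax ties (strain, ranking) break by scan order / ROI id —
  everything is deterministic; the only randomness anywhere is the
  seeded phantom noise.
- A boundary node whose exposed edge normals cancel (diagonal pinch)
  takes the normal of its highest-intensity incident edge.
- ROI pixels outside the foreground are dropped with a warning; an ROI
  with no foreground overlap, an empty foreground, a zero-intensity
  foreground pixel, and an ROI already spanning several components are
  errors.
- Problem sizes in tests and the acceptance script (blocks of 8–60
  pixels, rasters up to ~70x140) were chosen as the smallest instances
  that exhibit every behaviour of interest — thin necks, multi-joint
  chains, decoys, and a 20x span of node counts for the scaling trend.

## Known limitations

- 2D only; the voxel extension is structurally analogous but not
  implemented.
- The method prefers high aspect ratio around the cut: an isotropic
  blob strains too uniformly for a clean argmax trail.
- One global threshold; no adaptive foreground extraction.
- Gradient ascent is local; with a poor initial load it can stall at a
  stationary point (flagged in the trace). No restarts are attempted.
- Wall-clock grows superlinearly in node count (measured exponent
  ~1.4 over the tested range) because each removal refactorizes the
  system; caching factorization updates across removals is future
  work.
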