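# mig — geometry of γ-TuRC-capped microtubule minus ends

`mig` is a Python toolkit for the quantitative questions that arise when a
γ-tubulin ring complex (γ-TuRC) caps a microtubule minus end: how closed is
the 14-spoke ring, how do the 13 protofilaments of the emanating microtubule
sit relative to the ring and to each other, where is (or will be) the seam,
how many protofilaments does a filament in a projection image have, and how
strongly is a minus-end binding protein (e.g. CAMSAP2) enriched at the
capped end.  It is written for structural biologists and image analysts who
have atomic models, density maps, micrograph cut-outs or fluorescence line
profiles of such assemblies — and it ships a synthetic-assembly generator so
that every stage can be exercised and validated end-to-end with known ground
truth and no downloads.

## The quantities it computes

**Ring geometry.** The ring axis is the total-least-squares line through
four anchor centroids over spokes 1–13 (γ-tubulin Thr145 and Tyr152, plus
two per-GCP residue sets), fitted on the hypothetical fully closed
reference and oriented from the GCP base to the γ-tubulin layer.  Per-spoke
cylindrical coordinates (radius r, azimuth φ, height z) give pitch and
rotation increments; a microtubule-compatible ring has Δφ = 360°/13 ≈ 27.69°
and Δz = 3·41/13 ≈ 9.46 Å per spoke.  Ring *closure* is the in-plane
separation of the spoke-1 and spoke-14 γ-tubulins (zero when closed), and
per-spoke deviations from the closed reference are Euclidean distances
between matched γ-tubulin centres of mass after aligning on spokes 3–9.

**Protofilament lattice.** Wall building follows dock → rotate → register:
rigid-body docking by model-vs-map cross-correlation over a local pose
grid; per-protofilament rotation about its own axis to minimize the lateral
contact-pair distance (β-tubulin Tyr283↔Ala56 in atomistic models); axial
registration by scanning the correlation along the axis and resolving the
periodic peaks (one per 41 Å tubulin monomer) by simultaneous multi-Gaussian
fitting.

**Seam register.** Lateral contacts are homotypic (α–α/β–β), heterotypic
(α–β, the seam) or gaps.  Axial residuals modulo the 82 Å dimer repeat,
with per-interface species parity (the cyclic closure interface of a
3-start lattice has its registers swapped), yield the minimal axial
movement a protofilament needs to form a seam toward either neighbour.

**Protofilament number.** Moiré patterns are visualized by Fourier masking,
and segments are classified by maximal normalized cross-correlation against
synthetic projections of 11–16-protofilament walls low-pass filtered to
15 Å, with per-filament majority consensus and binomial fractions ±
sqrt(p(1−p)/n).  Also available as the sklearn-style estimator
`MoireProtofilamentClassifier`.

**Minus-end enrichment.** Segmented-line profiles (3 px width, spline,
0.13 µm sampling), background subtraction, lattice normalization,
peak-aligned averaging with t-based 95% CIs, and a one-tailed Welch t-test
of probe intensity within 0.6 µm of the γ-TuRC peak vs farther away.

## Worked example

```python
import numpy as np
from mig import synthetic_assembly as syn, ring_geometry as rg, seam_analysis as sa
from mig.pipeline import lattice_model_from_synthetic

# a partially closed ring (closure 0.47 between open and MT-compatible)
ring = syn.make_ring(syn.RingParams(closure=0.47))
sep = rg.closure_separation(ring.model)
print(f"spoke 1-14 in-plane separation: {sep/10:.2f} nm")

# a capped-minus-end emulation: the last protofilament sits 1.1 nm low and
# the protofilament at spoke 2 is 0.4 nm below seam register, contact-broken
lat = syn.make_mt_lattice(syn.LatticeParams(n_layers=8))
lat = syn.displace_protofilament(lat, 13, axial=-11.0)
lat = syn.displace_protofilament(lat, 1, axial=-4.0, radial=16.0)
lm = lattice_model_from_synthetic(lat)
contacts = sa.classify_lateral_contacts(lm, threshold=12.5)
print("gap interfaces:", [c.interface for c in contacts if c.type == "gap"])
rep = sa.seam_displacements(lm, 1)
print("toward pf13 (spoke 14):", rep.required_movement[13] / 10, "nm")
print("toward pf2  (spoke 3): ", round(rep.required_movement[2] / 10, 2), "nm")
print("prerequisites:", {k: v / 10 for k, v in rep.prerequisite_movements.items()})
print("seam prediction:", sa.predict_seam(contacts, lm).status,
      sa.predict_seam(contacts, lm).interfaces)
```

prints

```
spoke 1-14 in-plane separation: 2.49 nm
gap interfaces: [(1, 2), (13, 1)]
toward pf13 (spoke 14): 0.4 nm
toward pf2  (spoke 3):  3.7 nm
prerequisites: {13: 1.1}
seam prediction: candidates [(13, 1), (1, 2)]
```

The separation quantifies how far the ring is from template geometry; the
protofilament isolated by two gaps is the place the seam must form, and the
asymmetric movements (0.4 nm toward one neighbour, 3.7 nm toward the other —
the two seam registers differ by one 4.1 nm monomer) rank the two options.

## Command line

`mig` exposes each stage (`mig synth …`, `mig ring …`, `mig lattice …`,
`mig seam …`, `mig pfnum …`, `mig profile …`), a deterministic all-synthetic
run (`mig demo --seed 0 --out run/`), YAML-configured runs (`mig run
config.yaml`), and `mig reproduce paper-targets <models_dir>`, which
measures the headline minus-end quantities (ring separations, closed-
reference deviations, seam displacements) on user-supplied deposited
models (`open_ring.pdb` + `open_ring.yaml`, `capped_ring.*`,
`capped_lattice.*`; nothing is downloaded).

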