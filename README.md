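# acetograd

Quantification of microtubule-acetylation organisation in fluorescence
microscopy images: filament-network tracing, acetylated-fraction and
segment statistics, exponential gradient fitting, damage-site /
deacetylation-stretch geometry, and network-restricted Manders
colocalization — together with a synthetic cell-image simulator that
makes every stage testable by parameter recovery.

## The science

In adherent cells, acetylation of α-tubulin K40 marks long-lived
microtubule lattice.  It is organised as discrete acetylated segments
whose density decays exponentially with normalized distance x from the
nucleus edge (x = 0) to the plasma membrane (x = 1):

    Y(x) = Y₀ · exp(−x / λ)

with characteristic length λ ≈ 0.33 under resting conditions,
shallowing to λ ≈ 0.79 when an overexpressed, constitutively running
kinesin-1 motor distributes shaft damage uniformly.  Damage/repair sites
(recognised by a GTP-tubulin-conformation antibody) sit inside
deacetylated stretches; classifying aligned two-channel line scans at
50 a.u. yields stretch lengths (≈ 0.76 µm, ≈ 1.5-fold longer than the
damage sites) and center displacements (≈ 240 nm when not
colocalized).  The cytosolic deacetylase HDAC6 decorates the network but
overlaps acetylated segments for only ~20% of its network-bound signal
(Manders coefficient after restricting HDAC6 to the traced network).

The paper-scale numbers come from unreleased micrographs, so the package
validates itself on simulated cells whose generative parameters *are*
those numbers; each analysis must recover them.  See `docs/methods.md`
for the model, calibrations and known limitations.

## Worked example

```python
import acetograd as ag
from acetograd.metrics import analyze_cell
from acetograd.gradient import cell_radial_profile, pooled_lambda

cell, truth = ag.generate_cell(ag.preset("control"), seed=1)
summary = analyze_cell(cell)
print(f"traced acetylated fraction: {summary.ac_fraction:.2f} "
      f"(ground truth {truth.ac_fraction:.2f})")
print(f"mean segment length: {summary.mean_segment_um:.2f} µm, "
      f"{summary.segment_count} segments")

profiles = [cell_radial_profile(ag.generate_cell(ag.preset("control"), s)[0])
            for s in range(1, 13)]
fit = pooled_lambda(profiles)
print(f"fitted characteristic length λ = {fit.lambda_:.2f}")
```

prints (seed 1, twelve cells for the fit):

```
traced acetylated fraction: 0.34 (ground truth 0.31)
mean segment length: 2.38 µm, 70 segments
fitted characteristic length λ = 0.33
```

i.e. about a third of the network is acetylated, in ~2.5-µm segments,
and the pooled gradient decays with λ ≈ 0.33 of the nucleus-to-membrane
distance.

The numbered drivers under `analysis/` run the full study-style
analyses (simulation, gradient fits per condition, per-cell metrics,
damage geometry, colocalization) and write tables under `results/`.
There is also a CLI:

```bash
acetograd simulate --preset control --seed 7 --n-cells 3 --out cells/
acetograd segment cells/cell0007 --channel ac_tubulin
acetograd gradient cells/ --out gradient_out/
```

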