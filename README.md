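# foodspec

Visible-range (380–700 nm) reflectance spectroscopy is cheap, portable and
non-destructive, which makes it a candidate screening tool for food
authentication — checking that produce is the variety and cultivation class
it is sold as. This package implements the complete chemometric pipeline for
that task: spectral preprocessing, PLS-DA classification via a from-scratch
SIMPLS implementation, variable-importance (VIP) model inspection, two
evaluation protocols (repeated cross-validation and inter-session testing),
and a comparison against what a three-channel RGB camera would see. A
synthetic generator produces apple-like multi-session labelled spectra so
every stage can be exercised and tested end to end without instrument data.

## The method

Spectra are acquired as three scans at each of four positions per specimen;
scans are averaged per position. Each averaged spectrum **x** is then
preprocessed per row:

1. **zero correction** — x ← x − min(x), removing any constant ambient floor;
2. **two-norm normalization** — x ← x/‖x‖₂, cancelling the multiplicative
   intensity factor set by sensor–object distance and illumination;
3. **Savitzky–Golay smoothing** — local least-squares polynomial fit
   (order 3, window 31 points).

Classification is PLS-DA: class labels are dummy-coded into an indicator
matrix **Y**, and a partial-least-squares regression of **Y** on the spectra
matrix **X** is fitted with the SIMPLS algorithm, which extracts each
component from the dominant singular direction of the deflated cross-product
matrix **S** = **X**ᶜᵀ**Y**ᶜ. A sample is assigned to the class with the
largest continuous predicted response. The single hyperparameter is the
number of components *A*, scanned over 1–15 and chosen at peak accuracy.

Model inspection uses the VIP score per wavelength *j*,

VIPⱼ = √( p · Σₐ SSYₐ (wⱼₐ/‖wₐ‖)² / Σₐ SSYₐ ),

where SSYₐ is the Y-variance explained by component *a*; Σⱼ VIPⱼ² = p by
construction. The RGB comparison integrates each spectrum against a
camera's per-channel sensitivity functions (channel = Σ_λ S_c(λ)·x(λ)) and
re-runs the identical classification on the resulting three features,
quantifying the information a camera loses to metamerism.

## Worked example

```python
import foodspec as fs

cfg = fs.SimConfig(seed=42)            # 3 varieties x 44 specimens, 2 sessions
session1, session2 = [
    fs.preprocess_pipeline(fs.average_scans(s)) for s in fs.generate_dataset(cfg)
]
ecfg = fs.EvalConfig(k_folds=10, repeats=10,
                     components_range=tuple(range(1, 16)), seed=42)
for task in ("type", "organic"):
    curve = fs.repeated_cv(session1, ecfg, task=task)
    a = fs.select_components(curve)
    inter = fs.intersession_eval(session1, session2, ecfg, task=task)
    a2 = fs.select_components(inter)
    base = fs.zeror(fs.task_labels(session1.metas, task))
    print(f"{task}: CV {curve.accuracy_at(a):.1f}% at {a} comps "
          f"(ZeroR {base:.1f}%), inter-session {inter.accuracy_at(a2):.1f}% "
          f"at {a2} comps")

model = fs.fit_plsda(session1, fs.task_labels(session1.metas, "organic"), 4)
print(f"organic VIP peak: {fs.vip_scores(model).top_wavelength():.0f} nm")
```

prints

```
type: CV 100.0% at 2 comps (ZeroR 33.3%), inter-session 100.0% at 2 comps
organic: CV 97.5% at 5 comps (ZeroR 50.0%), inter-session 95.5% at 4 comps
organic VIP peak: 662 nm
```

The variety task is solved at 2 components, far above the 33.3%
majority-class baseline; the organic task is harder (its spectral signature
in the generator is a small shift of the chlorophyll-like 662 nm absorption
band) and needs more components. The VIP profile of the organic model peaks
at 662 nm — the model inspection recovers exactly the wavelength the
generator made informative.

The same experiments are available from a shell via the `foodspec` CLI
(`simulate`, `preprocess`, `crossval`, `intersession`, `vip`, `rgb`,
`predict`); run `foodspec --help`.

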