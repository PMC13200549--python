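# flowalign

Alignment of LC–MS feature maps and multidimensional NMR peak lists by
truncated-Wasserstein optimal transport, solved exactly as integer
min-cost flow with a Network Simplex algorithm.

## The problem

Replicate or comparative runs of the same sample never line up: analytes
elute at shifted retention times between LC–MS runs, and NMR resonances
drift between spectra with temperature, pH or instrument state (in
variable-temperature experiments those shifts *are* the signal — they
probe hydrogen bonding and conformational exchange). Downstream analysis
needs a map between corresponding signals that is robust to these shifts
and that leaves genuinely unmatched signal (noise, sample-specific
compounds) unmatched.

flowalign models each peak list as a discrete measure (peak positions
weighted by normalized intensity) and aligns two spectra by optimal
transport under a **truncated** ground cost:

$$
W_{\mathrm{tr}}(\rho,\nu)=\min_{\gamma\in\Gamma(\rho,\nu)}\int \hat d(x,y)\,\mathrm d\gamma, \qquad
\hat d(x,y)=\begin{cases} d(x-y) & d(x-y)\le d_{\max}\\ \delta_{\max} & \text{otherwise.}\end{cases}
$$

Mass moved between nearby peaks pays its distance; mass that cannot be
matched within $d_{\max}$ pays a flat penalty $\delta_{\max}$ via a
dedicated mismatch route. The problem is encoded as a sparse integer
min-cost-flow network (candidate pairs found by k-d tree inside radius
$\min(d_{\max},\delta_{\max})$; arcs costlier than $\delta_{\max}$
provably never carry flow) and solved exactly by a from-scratch Network
Simplex over Python integers, with an independent
successive-shortest-paths solver as a built-in cross-check oracle.

On top of the transport core sit the two front-ends (LC–MS axis
rescaling + consensus-pair reduction; NMR per-axis scaling + chain
alignment across spectral series), evaluation metrics (pairing
precision/recall against reliable identifications, and extended
confusion-matrix metrics that penalize unmatched peaks), and seeded
synthetic-data generators with known ground truth.

## Worked example

Two one-dimensional spectra — A with peaks at 0 and 10 (intensities 2 and
1), B with peaks at 1 and 30 — with $d_{\max}=\delta_{\max}=5$:

```python
>>> import flowalign as fa
>>> a = fa.Spectrum(positions=[[0.], [10.]], intensities=[2, 1],
...                 ids=("a0", "a1"), axes=("x",))
>>> b = fa.Spectrum(positions=[[1.], [30.]], intensities=[2, 1],
...                 ids=("b0", "b1"), axes=("x",))
>>> plan = fa.solve_transport(a, b, fa.TransportParams(d_max=5, delta_max=5))
>>> plan.total_cost
2.333332
>>> plan.matched
(('a0', 'b0', 0.666667, 1.0),)
>>> plan.mismatch_mass
0.333333
```

Only the 0↔1 pair lies within the radius, so 2/3 of the mass moves
distance 1 and the remaining 1/3 takes the mismatch route at cost 5:
$W_{\mathrm{tr}} = \tfrac23\cdot 1 + \tfrac13\cdot 5 = \tfrac73 \approx
2.333$ (the last digit reflects the $10^{-6}$ intensity quantization).

From the shell, on a synthetic variable-temperature series with known
ground truth:

```console
$ flowalign synth series --seed 7 --length 3 --prefix hsqc
wrote 3 spectra with 55 peaks each
$ flowalign align-nmr hsqc_t0.tsv hsqc_t1.tsv --dmax 0.05 --delta-max 0.09 --out pairs.tsv
$ head -9 pairs.tsv
# command	align-nmr
# d_max	0.05
# delta_max	0.09
# axis_scale	1.0,0.1
# match_fraction	0.5
# W_tr	0.015728022743
id_a	id_b	mass	distance	delta_axis0	delta_axis1
p0	p0	0.01549	0.0141089239	0.011980	0.074531
p1	p1	0.011652	0.0147904418	-0.011503	-0.092967
```

Every peak is matched to its true counterpart (ids coincide by
construction in the generator); `distance` is in the scaled metric (¹⁵N
axis × 0.1) while the `delta_*` columns are per-axis shifts in original
ppm. Chaining across the whole series tracks each resonance end-to-end
and reports its per-step shift trajectory:

```console
$ flowalign chain hsqc_t0.tsv hsqc_t1.tsv hsqc_t2.tsv --dmax 0.05 --delta-max 0.09 \
      --out chains.tsv --shifts-out shifts.tsv
$ head -6 chains.tsv
# command	chain
# d_max	0.05
# delta_max	0.09
# series_length	3
# chains	55
# full_length	55
```

All 55 chains reach full length. For LC–MS feature maps the analogous
entry point is `flowalign align-lcms A.featureXML B.featureXML
--max-mz-shift 0.005 --max-rt-shift 800`, which rescales the m/z axis by
`max_rt_shift/max_mz_shift` so both shift bounds become one radius, and
emits consensus feature pairs with their Δm/z and ΔRT. Further
subcommands: `wdist` (bare truncated-Wasserstein distance), `eval-lcms`,
`eval-extended`, `grid`, and `synth replicate|tile`.

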