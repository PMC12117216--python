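# Methods

`headphoton` simulates near-infrared photon migration through the whole
adult human head and reproduces the analysis chain of diametric
(transmission-geometry) optical measurements: voxel Monte Carlo transport,
time-of-flight (ToF) estimation, pathlength/attenuation metrics,
absorption-sensitivity Jacobians, and TCSPC photon-counting histogram
processing. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic phantoms do and do not show.

## Head phantom

The head is modelled as concentric ellipsoidal shells — scalp, skull,
cerebrospinal fluid (CSF), gray matter, white matter, optionally an
ellipsoidal air cavity — on a labelled voxel grid. This is an analytic
stand-in for MRI-derived anatomy: it preserves the topology that controls
photon migration (a thin, weakly scattering CSF shell sandwiched between
the strongly scattering skull and cortex), while remaining fully
parametric and requiring no external data. Subject-specific anatomy,
cortical folding and mesh-based geometry are out of scope; consequences
are discussed under Limitations.

Optical properties per layer (at 810 nm, 1/mm):

| layer        | mu_a   | mu_s    | g    | n    | mu_s' |
|--------------|--------|---------|------|------|-------|
| scalp (skin) | 0.045  | 19.818  | 0.89 | 1.37 | 2.180 |
| skull        | 0.011  | 17.4545 | 0.89 | 1.37 | 1.920 |
| CSF          | 0.0026 | 0.0909  | 0.89 | 1.37 | 0.010 |
| gray matter  | 0.028  | 7.3     | 0.89 | 1.37 | 0.803 |
| white matter | 0.092  | 38      | 0.87 | 1.37 | 4.940 |
| air cavities | 0      | 0       | 1    | 1    | 0     |

Geometry defaults: lateral (ear-to-ear) diameter 155 mm — the study
condition for the diametric measurement; anterior-posterior and
superior-inferior diameters default to 1.22x and 1.10x the lateral one
(standard adult proportions). Shell thicknesses (scalp 5, skull 7, CSF 3,
gray matter 4 mm; white matter fills the remainder) are configuration
values taken from typical adult-head literature, not measured inputs; all
are exposed as parameters. Voxel pitch defaults to 1 mm. Coordinates:
0-based voxel indices, physical positions are voxel centers in mm, label 0
is the exterior.

## Monte Carlo transport

Photon packets are launched from a uniformly filled collimated disk
(default 2 in. diameter, matching the enlarged source used to absorb
placement uncertainty) and tracked by a 3-D DDA voxel walk:

* Step sampling: a dimensionless optical step `s = -ln(1-u)` is consumed
  across voxels as `mu_s * l`; voxels with `mu_s = 0` (CSF is *almost*
  such a voxel; air cavities and the exterior exactly) are traversed
  ballistically.
* Implicit capture: weight is multiplied by `exp(-mu_a * l)` per traversed
  length; packets below the roulette threshold (default 1e-24) survive
  roulette with probability 0.1 and weight x10. The very low threshold is
  deliberate: diametric transmission attenuates by ~1e16-1e18, so packets
  must be allowed to decay that far before unbiased termination.
* Scattering: Henyey-Greenstein deflection with uniform azimuth;
  `g = 1` is treated as a forward delta, `|g| < 1e-7` as isotropic.
* Refractive boundaries: unpolarized Fresnel reflection/refraction decided
  probabilistically wherever `n` changes between adjacent voxels (all
  tissues share n = 1.37, so interior interfaces are matched; tissue/air
  and tissue/exterior interfaces reflect, with total internal reflection
  honored). Exterior traversal (before first entry) accumulates neither
  pathlength nor time, keeping `t = sum(path_i * n_i)/c` exact over the
  recorded per-layer paths.
* Clock: packets are killed at `max_time` (default 12.5 ns, one 80 MHz
  laser period — the TCSPC observation window).
* Fluence: absorbed-weight estimator `dw/(mu_a V)` per voxel, switching to
  the track-length estimator `w l / V` where `mu_a = 0`; values are per
  launched packet.
* Detection: a packet exiting through a surface face belonging to the
  detector patch (sphere-cap or depth-crop selection on the exterior-facing
  boundary faces) is recorded with weight, exit time, per-layer
  pathlengths, exit position/direction, and optionally its per-voxel
  pathlengths (sparse) and scattering-event trajectory. No numerical-
  aperture cut is applied at the detector (the study's simulated detector
  crops by surface region only).
* RNG: one xorshift64* stream per packet, seeded via splitmix64 from
  (seed, packet index). Runs are bitwise reproducible; results do not
  depend on batching.
* Every run is audited for energy conservation (launched = absorbed +
  exited + roulette-lost + time-expired + missed) to 1e-6 relative; a
  violation raises.

Verified against independent closed forms: ballistic crossing times,
normal-incidence Fresnel coefficients, the Henyey-Greenstein mean cosine,
the similarity relation (g=0 vs g=0.9 at matched mu_s'), the infinite-
medium diffusion Green's function (within 10% at 5-20 transport MFPs), and
the semi-infinite time-resolved reflectance Green's function (within 15%
near the peak).

## Pathlength metrics

For detected packets with weights `w_i` and per-layer paths `l_ij`:
`<path> = sum w_i path_i / sum w_i`; `DPF = <path>/SDD`; layer fractions
`f_j` are weight-weighted pathlength shares; `<mu_s'> = sum_j f_j mu_s'_j`
and likewise `<mu_a>`; the transport-MFP count is `SDD*(<mu_s'>+<mu_a>)`.
The weighted coefficient averages weight each layer by *weight x
pathlength*, not packet weight alone: a layer grazed for 0.1 mm should not
count like one traversed for 300 mm, and this weighting reproduces the
published transport-MFP count (~234 at SDD = 155 mm) from the published
layer fractions. A packet-weight-only variant is available
(`weighting="packet"`).

The diffusive Beer-Lambert bound for a slab is `exp(-mu_eff L)` with
`mu_eff = sqrt(3 mu_a (mu_a + mu_s'))`, reported as a base-10 exponent.
For the white-matter-only estimate (mu_a = 0.92/cm, mu_s' = 49.4/cm,
L = 10 cm) this evaluates to 10^-51.18. Discussions of this estimate
sometimes quote ~10^-53; that figure is not what the formula yields with
these coefficients, and this package reports the formula's value.

Etendue: `A*Omega = pi (d/2)^2 * pi NA^2`; the 5 mm sensor at NA = 0.52
gives 16.68 mm^2 sr.

## ToF estimation and TCSPC processing

The detected-packet ToF density is a weighted Gaussian KDE with Silverman
bandwidth `h = 0.9 min(sigma_w, IQR_w/1.34) n_eff^(-1/5)` using weighted
moments and `n_eff = (sum w)^2 / sum w^2`, then convolved with a unit-area
Gaussian IRF (default FWHM 300 ps). Time zero is the IRF peak.

The synthetic TCSPC generator emulates the study acquisition: 15 x 2-min
signal exposures at ~1 detected photon/s against a 15 cps dark rate,
4096 bins over the 12.5 ns window (~3.05 ps/bin, making the 251-bin filter
window ~0.77 ns), with one background reading per five signal exposures.
Counts are Poisson: per bin, mean `exposure*(signal_rate*density*bin_width
+ background_rate/n_bins)`; the background stack omits the signal term.
Processing follows the experimental order of operations: per-bin mean
background is subtracted from the mean signal, the result is smoothed with
a Savitzky-Golay filter (window 251, order 3, mirror padding), the per-bin
SEM is computed across exposures *before* filtering, and the upper/lower
bands are the filtered (mean +/- SEM). The alternative reading — adding
the filtered SEM after filtering — is available via `band_center="raw"`.

A noise-floor note: with the 1-in-5 interleave only 3 background exposures
estimate the per-bin background mean, and at 1 cps signal vs 15 cps dark
that subtraction noise alone limits the correlation between the filtered
trace and the true density to ~0.85. The end-to-end fidelity check of the
chain therefore uses an equal background schedule; at the default
interleave the peak position is still recovered to well within two filter
windows.

What the generator does not emulate: detector pile-up and dead time,
afterpulsing, IRF asymmetry, drift between exposures, and ambient-leak
transients — so passing checks demonstrate the correctness of the
processing chain, not robustness to those instrument effects.

## Absorption Jacobian

First-order perturbation Monte Carlo on the recorded paths:
`J(v) = dI/dmu_a(v) = -sum_i w_i L_i(v)` with `L_i(v)` the packet's exact
pathlength in voxel `v` (sparse per-packet accumulation; exact lengths,
not step counts). It is validated against common-seed finite differences
(+5% mu_a in slab regions of a 20 mm cube; correlation > 0.95 and
first-order magnitude agreement), and qualitatively reproduces the
source-repositioning behaviour: lowering the source shifts |J| mass below
the mid-axial plane, and the CSF layer's share of |J| exceeds its volume
share (guiding concentrates sensitivity).

## Problem sizes

The study's simulation campaign aggregated 7.24e13 photon packets on GPUs;
that scale is out of scope here. Desk-scale sizes used by the test suite
and the acceptance script: 3.5e6 packets (suite) / 3e6 (acceptance script)
for the diametric 155 mm transmission at 1 mm pitch, 2.5e5-packet runs for
Jacobian maps, 7e5 for the semi-infinite reflectance oracle and 2.5e4 for
the infinite-medium oracle. At these sizes the diametric detector patch
collects of order 10 packets whose weights span many decades, so the
weighted DPF and layer fractions are stochastic: the DPF lands in a broad
band around the published 6.5 rather than at a converged value (across
seeds at 1e6 packets we observed roughly 7-11 with an effective sample
size near 1), and the per-layer fractions fluctuate by tens of percent
relative. The deep (>~60 mm) portion of the fluence-depth curve spans
1e16-1e18 of attenuation and is not statistically resolved at desk scale.

## Known limitations

* Ellipsoidal shells cannot reproduce subject anatomy; DPF and layer
  fractions are geometry-sensitive, so quantitative agreement with
  measured heads is bracketed, not exact.
* Single wavelength; no chromophore model, no polarization, no
  fluorescence.
* Voxelized interfaces rasterize curved boundaries; Fresnel normals are
  face-aligned. At 1 mm pitch this biases guided CSF paths slightly
  relative to smooth-surface meshes.
* The detector model is a surface patch with full angular acceptance; an
  NA cut is available but off by default.
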