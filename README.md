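# arborsplit

Automatic tracing of singly-stained neurons from 3-D fluorescence image
stacks, with a mask-based decomposition step for the case automatic tracers
handle worst: two arbors of the same neuron ramifying through the same
region of tissue.

## Who this is for

Neuroanatomists reconstructing neuron morphology from confocal stacks
(anisotropic voxels, e.g. 0.36 × 0.36 × 1 μm) who want a scriptable,
reproducible alternative to fully manual tracing. The package produces SWC
trees, converts them to legacy-VTK polylines for ParaView, and quantifies
reconstruction quality against a gold standard.

## The method

**Basic scheme.** The stack is optionally deconvolved (Richardson–Lucy with
a Gaussian-approximated PSF), thresholded, and split into connected
components. Fragments with volume ≤ VT voxels (default VT = 30) are
discarded. On the largest fragment a neurite terminal is selected
automatically as the seed — an endpoint of a longest geodesic path through
the foreground. A centerline tree grows from that single seed by a geodesic
distance transform: the farthest uncovered voxel is back-traced to the
skeleton along medially-weighted shortest paths, the surrounding tube is
marked covered, and the process repeats. Node radii are the Euclidean
distance to background; remaining fragments are attached whenever their
voxel gap, rounded to the nearest integer, is < DT (default DT = 30).

**Revised scheme.** When two arbors overlap, the merged foreground misleads
any single-seed tracer. A binary mask covering one arbor (drawn manually in
a tool such as ITK-SNAP, or produced by the synthetic oracle) splits the
image losslessly: the voxelwise logical product (AND) of image and mask
extracts that arbor's partial image, and a value-equality exclusive-or (EOR)
of image and partial leaves the complement — `AND(I,M) + EOR(I, AND(I,M)) = I`
voxel-exactly. Each partial image is traced independently and the partial
reconstructions are re-merged into one tree. The procedure applies
recursively for more than two entangled arbors.

**Scoring.** Reconstructions are compared to a gold standard with a
gold-centric metric in [0, 1]: the gold tree's critical nodes (bifurcations
and terminals) are matched one-to-one against test nodes under lateral and
axial position thresholds plus a path-length consistency check, each node
weighted by its number of terminal descendants. 1 means a perfect match,
0 completely unmatched.

## Worked example

Simulate the hard case — two arbors sharing a primary neurite and
interdigitating distal to the bifurcation — then trace it both ways and
score against the generated ground truth:

```sh
arborsplit simulate --scenario overlapping --seed 2 --out-dir demo
arborsplit trace demo/image.tif --out demo/basic.swc
arborsplit trace-separated demo/image.tif --mask demo/mask_arborA.tif --out demo/revised.swc
arborsplit score demo/basic.swc demo/gold.swc
arborsplit score demo/revised.swc demo/gold.swc
```

prints

```
score   0.606
matched 19/35 critical nodes
score   1.000
matched 35/35 critical nodes
```

The basic scheme misconnects branches where the two arbors touch, so only
19 of the 35 gold bifurcations/terminals are reproduced with consistent
path lengths (score 0.606). With the oracle mask separating one arbor
before tracing, every critical node is recovered (score 1.000). Across ten
seeded scenarios the revised scheme outscores the basic one in 9 of 10 with
median 0.93 vs 0.61.

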