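#!/usr/bin/env bash
# Full command-line workflow: simulate a small dataset, then run the
# comparison pipeline from a YAML config. Artifacts land in scratch/.
set -euo pipefail

OUT=scratch/example-cli
rm -rf "$OUT"
mkdir -p "$OUT"

# 1. simulate a 6-specimen population with known ground truth
morphosurf simulate -o "$OUT/pop" --subdivisions 2 --n-landmarks 12 \
    -k 30 -n 6 --seed 1

# 2. write a run configuration
cat > "$OUT/run.yaml" <<EOF
dataset_manifest: $OUT/pop/manifest.csv
template_mesh: $OUT/pop/template_mesh.ply
template_landmarks: $OUT/pop/template_landmarks.csv
template_semilandmarks: $OUT/pop/template_semis.csv
methods: [sliding_tps, ls_icp]
densities: [15, 30]
targets: [mean, landmark-only]
output_dir: $OUT/run
EOF

# 3. execute the full comparison run (tables, surfaces, maps, manifest)
morphosurf -v run -c "$OUT/run.yaml"

# 4. compare the two methods' max-density means directly
morphosurf compare "$OUT/run/surfaces/mean_sliding_tps_k30.ply" \
    "$OUT/run/surfaces/mean_ls_icp_k30.ply"

echo "artifacts:"
find "$OUT/run" -type f | sort
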