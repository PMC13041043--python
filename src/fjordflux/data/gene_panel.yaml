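# Default nitrogen-cycle gene panel: gene symbol -> process, plus the
# single-copy reference genes used for Average Genomic Copy Number.
references: [recA, gyrB, rpoB]
genes:
  nifH: nitrogen fixation
  amoA: nitrification
  amoB: nitrification
  hao: nitrification
  nosZ: denitrification
  nirK: denitrification
  norB: denitrification
  hdh: anammox
  napA: nitrate/nitrite reduction
  nirD: nitrate/nitrite reduction
  narB: assimilatory nitrate reduction
  nasA: assimilatory nitrate reduction
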