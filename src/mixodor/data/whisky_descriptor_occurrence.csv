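descriptor,top5_occurrence
solvent-like,8
apple-like,9
flowery,2
butter-like,3
fruity,13
honey-like,5
caramel-like,6
peach-like,3
smoky,4
phenolic,5
vanilla-like,3
pear-like,7
woody,3
honeydew-melon-like,2
coconut-like,0
spicy-clove-like,3
orange-like,4
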