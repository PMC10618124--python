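code,durable
finished_brick,1
concrete_block,1
concrete_slab,1
cement,1
tiles,1
metal_sheet,1
wood_finished,1
adobe_finished,1
wood_planks,0
unfinished_surface,0
tarpaulin,0
scrap_metal,0
thatch,0
earth,0
sand,0
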