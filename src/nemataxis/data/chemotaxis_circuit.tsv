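# Curated approximation of the C. elegans salt-chemotaxis circuit over the
# 22-neuron set (ASE, AIA, AIB, AIY, AIZ, RIA, RIB, RIM, RIV, AVB, PVC
# left/right pairs).  Directed chemical synapses (type=chem), undirected gap
# junctions listed once (type=gap), and external drives (type=input):
# I1 = encoded ASEL drive, I2 = encoded ASER drive, q0 = head-bending angle
# delivered through RIV.  This list is a hand-curated, replaceable
# approximation, not an exact extraction of the published wiring diagram;
# the RIV->RIA and RIV->AIZ rows are added so the head-bend signal reaches
# the neurons assigned to the perpendicular-gradient output.
# pre	post	type
I1	ASEL	input
I2	ASER	input
q0	RIVL	input
q0	RIVR	input
ASEL	AIYL	chem
ASEL	AIYR	chem
ASER	AIYL	chem
ASER	AIYR	chem
ASEL	AIAL	chem
ASER	AIAR	chem
ASEL	AIBL	chem
ASER	AIBR	chem
AIAL	AIBL	chem
AIAR	AIBR	chem
AIYL	AIZL	chem
AIYR	AIZR	chem
AIYL	AIZR	chem
AIYR	AIZL	chem
AIZL	RIAL	chem
AIZR	RIAR	chem
AIZL	RIBL	chem
AIZR	RIBR	chem
AIZL	RIML	chem
AIZR	RIMR	chem
AIBL	RIML	chem
AIBL	RIBL	chem
AIBR	RIMR	chem
AIBR	RIBR	chem
RIBL	AVBL	chem
RIBR	AVBR	chem
RIBL	AVBR	chem
RIBR	AVBL	chem
RIML	RIVL	chem
RIMR	RIVR	chem
RIAL	RIVL	chem
RIAR	RIVR	chem
RIVL	RIAL	chem
RIVR	RIAR	chem
RIVL	AIZL	chem
RIVR	AIZR	chem
AVBL	PVCL	chem
AVBR	PVCR	chem
PVCL	AVBL	chem
PVCR	AVBR	chem
AIAL	AIAR	gap
AIYL	AIYR	gap
AIZL	AIZR	gap
RIAL	RIAR	gap
RIVL	RIVR	gap
RIML	RIMR	gap
AIBL	RIML	gap
AIBR	RIMR	gap
AVBL	AVBR	gap
PVCL	AVBL	gap
PVCR	AVBR	gap
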