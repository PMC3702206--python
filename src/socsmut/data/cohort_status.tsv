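case_id	socs1_status
MPI-135	mutant
MPI-202	mutant
MPI-166	mutant
MPI-247	mutant
MPI-030	mutant
MPI-165	mutant
MPI-199	mutant
MPI-063	mutant
MPI-092	mutant
MPI-157	mutant
MPI-046	mutant
MPI-134	mutant
MPI-105	mutant
MPI-241	mutant
MPI-122	mutant
MPI-220	mutant
MPI-248	mutant
MPI-136	mutant
MPI-137	mutant
MPI-207	mutant
MPI-036	mutant
MPI-153	mutant
MPI-102	mutant
MPI-109	mutant
WT-001	wild_type
WT-002	wild_type
WT-003	wild_type
WT-004	wild_type
WT-005	wild_type
WT-006	wild_type
WT-007	wild_type
WT-008	wild_type
WT-009	wild_type
WT-010	wild_type
WT-011	wild_type
WT-012	wild_type
WT-013	wild_type
WT-014	wild_type
WT-015	wild_type
WT-016	wild_type
WT-017	wild_type
WT-018	wild_type
WT-019	wild_type
WT-020	wild_type
WT-021	wild_type
WT-022	wild_type
WT-023	wild_type
WT-024	wild_type
WT-025	wild_type
WT-026	wild_type
WT-027	wild_type
WT-028	wild_type
WT-029	wild_type
WT-030	wild_type
WT-031	wild_type
WT-032	wild_type
WT-033	wild_type
WT-034	wild_type
WT-035	wild_type
WT-036	wild_type
WT-037	wild_type
WT-038	wild_type
WT-039	wild_type
WT-040	wild_type
WT-041	wild_type
WT-042	wild_type
WT-043	wild_type
WT-044	wild_type
WT-045	wild_type
WT-046	wild_type
WT-047	wild_type
WT-048	wild_type
WT-049	wild_type
WT-050	wild_type
WT-051	wild_type
WT-052	wild_type
WT-053	wild_type
WT-054	wild_type
WT-055	wild_type
WT-056	wild_type
WT-057	wild_type
WT-058	wild_type
WT-059	wild_type
WT-060	wild_type
WT-061	wild_type
WT-062	wild_type
WT-063	wild_type
WT-064	wild_type
WT-065	wild_type
WT-066	wild_type
WT-067	wild_type
WT-068	wild_type
WT-069	wild_type
WT-070	wild_type
WT-071	wild_type
WT-072	wild_type
WT-073	wild_type
WT-074	wild_type
WT-075	wild_type
WT-076	wild_type
WT-077	wild_type
WT-078	wild_type
WT-079	wild_type
WT-080	wild_type
WT-081	wild_type
WT-082	wild_type
WT-083	wild_type
WT-084	wild_type
WT-085	wild_type
WT-086	wild_type
WT-087	wild_type
WT-088	wild_type
WT-089	wild_type
WT-090	wild_type
WT-091	wild_type
WT-092	wild_type
WT-093	wild_type
WT-094	wild_type
WT-095	wild_type
WT-096	wild_type
WT-097	wild_type
WT-098	wild_type
WT-099	wild_type
WT-100	wild_type
WT-101	wild_type
WT-102	wild_type
WT-103	wild_type
WT-104	wild_type
WT-105	wild_type
WT-106	wild_type
WT-107	wild_type
WT-108	wild_type
WT-109	wild_type
WT-110	wild_type
WT-111	wild_type
WT-112	wild_type
WT-113	wild_type
WT-114	wild_type
WT-115	wild_type
WT-116	wild_type
WT-117	wild_type
WT-118	wild_type
WT-119	wild_type
WT-120	wild_type
WT-121	wild_type
WT-122	wild_type
WT-123	wild_type
WT-124	wild_type
WT-125	wild_type
WT-126	wild_type
WT-127	wild_type
WT-128	wild_type
WT-129	wild_type
WT-130	wild_type
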