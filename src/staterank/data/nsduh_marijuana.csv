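state,prevalence_pct,se_pct,published_rank
Alabama,7.6,0.9,43
Alaska,12.4,1.3,13
Arizona,11.5,1.1,18
Arkansas,8.7,1.2,35
California,11.3,0.6,19
Colorado,16.8,1.6,2
Connecticut,12.0,1.3,15
Delaware,11.0,1.2,20
District of Columbia,14.7,1.1,5
Florida,9.4,0.5,30
Georgia,10.0,1.1,25
Hawaii,12.2,1.2,14
Idaho,9.4,1.2,30
Illinois,9.3,0.6,30
Indiana,10.2,1.0,24
Iowa,7.5,1.0,44
Kansas,8.4,1.1,37
Kentucky,7.7,1.1,43
Louisiana,6.3,0.9,50
Maine,12.8,1.2,11
Maryland,11.6,1.2,17
Massachusetts,13.9,1.2,7
Michigan,12.4,0.7,13
Minnesota,8.3,1.0,38
Mississippi,7.2,0.9,46
Missouri,9.5,1.0,29
Montana,12.4,1.3,13
Nebraska,7.5,0.8,44
Nevada,12.5,1.3,13
New Hampshire,13.9,1.1,7
New Jersey,9.1,1.0,32
New Mexico,12.5,1.3,13
New York,11.4,0.6,18
North Carolina,8.9,1.1,34
North Dakota,7.9,1.1,41
Ohio,9.0,0.5,33
Oklahoma,7.9,1.2,41
Oregon,13.6,1.3,8
Pennsylvania,10.3,0.7,24
Rhode Island,18.7,1.6,1
South Carolina,8.6,0.9,36
South Dakota,8.2,1.1,39
Tennessee,7.7,0.9,43
Texas,9.3,0.6,30
Utah,6.3,1.4,50
Vermont,16.7,1.4,3
Virginia,7.7,1.0,43
Washington,14.6,1.5,5
West Virginia,7.7,0.8,43
Wisconsin,11.7,1.2,17
Wyoming,8.5,1.1,37
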